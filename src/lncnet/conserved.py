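"""Cross-group conserved-interaction extraction.

From the TOM submatrix of each group's trait-associated module:
enumerate all within-module pairs, intersect pairs across groups, keep
only mRNA-mRNA and lncRNA-mRNA pairs touching a common gene, and retain
pairs whose TOM weight is in the top quantile in every group
simultaneously.  Pairs are unordered; endpoints are stored sorted.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .catalog import TranscriptClass, is_lncrna

PAIR_MRNA_MRNA = "mRNA-mRNA"
PAIR_LNC_MRNA = "lncRNA-mRNA"
PAIR_LNC_LNC = "lncRNA-lncRNA"
PAIR_OTHER = "other"

RETAINED_PAIR_TYPES = frozenset({PAIR_MRNA_MRNA, PAIR_LNC_MRNA})


def interactions_from_module(
    tom: pd.DataFrame, module_transcripts: Iterable[str] | None = None
) -> pd.DataFrame:
    """All unordered off-diagonal pairs of the (sub)matrix with weights.

    Returns a DataFrame with columns a, b (a < b lexicographically) and
    weight; m transcripts yield m(m-1)/2 rows.  Fewer than two
    transcripts yield an empty frame.
    """
    if module_transcripts is not None:
        members = [t for t in tom.index if t in set(module_transcripts)]
        tom = tom.loc[members, members]
    ids = np.array(tom.index)
    m = len(ids)
    if m < 2:
        return pd.DataFrame(columns=["a", "b", "weight"])
    iu, ju = np.triu_indices(m, k=1)
    a, b = ids[iu], ids[ju]
    swap = a > b
    a2 = np.where(swap, b, a)
    b2 = np.where(swap, a, b)
    return pd.DataFrame(
        {"a": a2, "b": b2, "weight": tom.to_numpy()[iu, ju]}
    )


def intersect_common(per_group: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairs present in every group, carrying each group's weight.

    Input: group -> pair frame (columns a, b, weight).  Output columns:
    a, b, weight_<group> for each group.
    """
    if len(per_group) < 2:
        raise ValueError("need pair lists from at least 2 groups")
    merged = None
    for g, df in per_group.items():
        part = df.rename(columns={"weight": f"weight_{g}"})[["a", "b", f"weight_{g}"]]
        merged = part if merged is None else merged.merge(part, on=["a", "b"])
    return merged.reset_index(drop=True)


def _pair_type(cls_a: str, cls_b: str) -> str:
    lnc_a, lnc_b = is_lncrna(cls_a), is_lncrna(cls_b)
    mrna_a = TranscriptClass(cls_a) == TranscriptClass.KNOWN_MRNA
    mrna_b = TranscriptClass(cls_b) == TranscriptClass.KNOWN_MRNA
    if lnc_a and lnc_b:
        return PAIR_LNC_LNC
    if mrna_a and mrna_b:
        return PAIR_MRNA_MRNA
    if (lnc_a and mrna_b) or (mrna_a and lnc_b):
        return PAIR_LNC_MRNA
    return PAIR_OTHER


def annotate_pairs(common: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Add pair_type and per-endpoint gene ids from the catalog table."""
    endpoints = set(common["a"]) | set(common["b"])
    missing = sorted(endpoints - set(catalog.index))
    if missing:
        raise ValueError(f"pair endpoints missing from catalog: {missing[:10]}")
    cls = catalog["assigned_class"]
    gene = catalog["gene_id"]
    out = common.copy()
    out["pair_type"] = [
        _pair_type(cls[a], cls[b]) for a, b in zip(out["a"], out["b"])
    ]
    out["gene_a"] = gene[out["a"]].to_numpy()
    out["gene_b"] = gene[out["b"]].to_numpy()
    return out


def filter_type_and_genes(
    common: pd.DataFrame,
    catalog: pd.DataFrame,
    common_genes: Iterable[str],
    mode: str = "any",
) -> pd.DataFrame:
    """Keep mRNA-mRNA / lncRNA-mRNA pairs related to the common genes.

    ``mode="any"`` requires at least one endpoint's gene in
    *common_genes*; ``mode="both"`` requires both.
    """
    if mode not in {"any", "both"}:
        raise ValueError("mode must be 'any' or 'both'")
    annotated = annotate_pairs(common, catalog)
    common_genes = set(common_genes)
    type_ok = annotated["pair_type"].isin(RETAINED_PAIR_TYPES)
    in_a = annotated["gene_a"].isin(common_genes)
    in_b = annotated["gene_b"].isin(common_genes)
    gene_ok = (in_a | in_b) if mode == "any" else (in_a & in_b)
    return annotated[type_ok & gene_ok].reset_index(drop=True)


def top_quantile_filter(filtered: pd.DataFrame, q: float = 0.20) -> pd.DataFrame:
    """Keep pairs in the top *q* weight quantile of EVERY group.

    Per group the threshold is the (1 - q) linear-interpolation quantile
    of that group's weights over the filtered set; retention requires
    weight >= threshold simultaneously in all groups.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must be in (0, 1]")
    weight_cols = [c for c in filtered.columns if c.startswith("weight_")]
    if not weight_cols:
        raise ValueError("no per-group weight columns found")
    if len(filtered) == 0:
        return filtered.copy()
    keep = np.ones(len(filtered), dtype=bool)
    for col in weight_cols:
        thr = np.quantile(filtered[col].to_numpy(), 1.0 - q)
        keep &= filtered[col].to_numpy() >= thr
    return filtered[keep].reset_index(drop=True)


def build_conserved_network(
    final: pd.DataFrame, common_genes: Iterable[str] = ()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge list (mean weight across groups) and node table with degrees."""
    weight_cols = [c for c in final.columns if c.startswith("weight_")]
    edges = final.copy()
    if len(edges):
        edges["mean_weight"] = edges[weight_cols].mean(axis=1)
    else:
        edges["mean_weight"] = pd.Series(dtype=float)

    common_genes = set(common_genes)
    node_rows: dict[str, dict] = {}
    for _idx, row in edges.iterrows():
        for end, gene_col in (("a", "gene_a"), ("b", "gene_b")):
            tid = row[end]
            info = node_rows.setdefault(
                tid,
                {
                    "gene_id": row.get(gene_col, tid),
                    "degree": 0,
                    "in_common_genes": row.get(gene_col, tid) in common_genes,
                },
            )
            info["degree"] += 1
    nodes = pd.DataFrame.from_dict(node_rows, orient="index")
    nodes.index.name = "transcript_id"
    return edges, nodes


def conserved_pipeline(
    module_toms: Mapping[str, pd.DataFrame],
    catalog: pd.DataFrame,
    common_genes: Iterable[str],
    q: float = 0.20,
    mode: str = "any",
) -> dict:
    """Run the full funnel; returns a dict with every intermediate stage."""
    per_group = {g: interactions_from_module(t) for g, t in module_toms.items()}
    common = intersect_common(per_group)
    filtered = filter_type_and_genes(common, catalog, common_genes, mode=mode)
    final = top_quantile_filter(filtered, q=q)
    edges, nodes = build_conserved_network(final, common_genes)
    return {
        "per_group": per_group,
        "common": common,
        "filtered": filtered,
        "final": final,
        "edges": edges,
        "nodes": nodes,
        "funnel": {
            "common": len(common),
            "filtered": len(filtered),
            "final": len(final),
        },
    }
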