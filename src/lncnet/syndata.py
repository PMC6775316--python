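"""Synthetic multi-group RNA-seq data with planted structure.

The generator produces, for a configurable number of treatment groups
sharing one merged control block: negative-binomial count matrices with
planted co-expression modules driven by latent factors, a binary trait
that shifts the trait-associated module in treated samples, transcript
records (sequences, annotation, coding evidence) whose catalog classes
are known by construction, gene sets with one planted enriched set, and
a ground-truth channel for recovery tests.

Model: each module m has one latent factor f_m per sample, f ~ N(0,1);
treated samples add ``trait_effect`` to the trait module's factor.  A
transcript in module m has latent profile

    z_gs = sqrt(rho) * f_m(s) + sqrt(1 - rho) * eps_gs,

background transcripts are pure noise.  Planted conserved pairs are the
hubs of per-pair sub-cliques inside the trait module: each pair anchors
a sub-factor (correlated across cliques through the module factor), its
endpoints load sqrt(within_pair_cor) on it and satellite members load
sqrt(within_module_cor).  Counts are NB(mu, alpha) with
mu_gs = exp(base_g + log_sd * z_gs) and Var = mu + alpha * mu^2.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io
from .catalog import (
    MAX_NONCODING_ORF_AA,
    CodingEvidence,
    TranscriptClass,
    TranscriptRecord,
    _scan_forward_frames,
)
from .enrich import GeneSetCollection

_NT = np.array(list("ACGT"))
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
]


class ConfigError(ValueError):
    """Raised for invalid synthetic-data configurations."""


@dataclass
class SyntheticConfig:
    n_samples_treated: int = 8
    n_samples_control: int = 8
    n_groups: int = 3
    n_mrna: int = 220
    n_lncrna: int = 80
    n_modules: int = 3
    module_sizes: tuple[int, ...] = (60, 50, 40)
    trait_effect: float = 2.0
    within_module_cor: float = 0.8
    within_pair_cor: float = 0.95
    nb_dispersion: float = 0.1
    mean_log_expr_mrna: float = 5.5
    mean_log_expr_lnc: float = 4.0
    log_sd: float = 1.0
    n_conserved_pairs: int = 10
    pair_clique_cor: float = 0.7  # cor between planted-pair sub-factors
    known_lnc_fraction: float = 0.5
    n_decoys: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        self.validate()

    def validate(self) -> None:
        positive = {
            "n_samples_treated": self.n_samples_treated,
            "n_samples_control": self.n_samples_control,
            "n_groups": self.n_groups,
            "n_mrna": self.n_mrna,
            "nb_dispersion": self.nb_dispersion,
        }
        for name, val in positive.items():
            if val <= 0:
                raise ConfigError(f"{name} must be positive, got {val}")
        if self.n_lncrna < 0 or self.n_conserved_pairs < 0 or self.n_decoys < 0:
            raise ConfigError("counts must be non-negative")
        if len(self.module_sizes) != self.n_modules:
            raise ConfigError("module_sizes length must equal n_modules")
        if any(s < 2 for s in self.module_sizes):
            raise ConfigError("module sizes must be >= 2")
        if sum(self.module_sizes) > self.n_mrna + self.n_lncrna:
            raise ConfigError("sum(module_sizes) exceeds transcript count")
        if not 0.0 <= self.within_module_cor <= 1.0:
            raise ConfigError("within_module_cor must be in [0, 1]")
        if not self.within_module_cor <= self.within_pair_cor <= 1.0:
            raise ConfigError("within_pair_cor must be in [within_module_cor, 1]")
        if not 0.0 < self.pair_clique_cor < 1.0:
            raise ConfigError("pair_clique_cor must be in (0, 1)")
        if self.trait_effect < 0:
            raise ConfigError("trait_effect must be >= 0")
        if self.mean_log_expr_lnc >= self.mean_log_expr_mrna:
            raise ConfigError("lncRNA mean log expression must be below mRNA mean")
        if self.n_conserved_pairs > 0:
            if 2 * self.n_conserved_pairs > self.module_sizes[0]:
                raise ConfigError("trait module too small for planted pairs")
            if self.n_conserved_pairs > min(self.n_lncrna, self.n_mrna):
                raise ConfigError("not enough transcripts for planted pairs")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "module_sizes" in data:
            data["module_sizes"] = tuple(data["module_sizes"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["module_sizes"] = list(self.module_sizes)
        return d


@dataclass
class GroundTruth:
    """Per-transcript truth and planted structure, for recovery tests."""

    rna_type: dict[str, str]  # transcript -> "mRNA" | "lncRNA"
    expected_class: dict[str, str]  # transcript -> catalog class value
    module_label: dict[str, int]  # transcript -> module id (0 = background)
    trait_modules: dict[str, int]  # group -> trait-associated module id
    conserved_pairs: list[tuple[str, str]]  # planted (lncRNA, mRNA) pairs
    gene_of: dict[str, str]  # transcript -> gene id
    planted_set_name: str
    groups: list[str]

    def to_json(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["conserved_pairs"] = [list(p) for p in self.conserved_pairs]
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["conserved_pairs"] = [tuple(p) for p in data["conserved_pairs"]]
        return cls(**data)


@dataclass
class Dataset:
    config: SyntheticConfig
    counts: dict[str, pd.DataFrame]  # group -> transcripts x samples
    samples: dict[str, pd.DataFrame]  # group -> sample table
    records: list[TranscriptRecord]
    truth: GroundTruth
    gene_sets: GeneSetCollection


def nb_counts(rng: np.random.Generator, mu, alpha: float) -> np.ndarray:
    """Negative-binomial draws with mean mu and Var = mu + alpha * mu^2."""
    if alpha <= 0:
        raise ConfigError("nb_dispersion must be positive")
    mu = np.asarray(mu, dtype=float)
    shape = 1.0 / alpha
    return rng.negative_binomial(shape, shape / (shape + mu))


# ---------------------------------------------------------------------------
# layout plan (shared by counts and records so they agree on the truth)

@dataclass
class _Plan:
    transcript_ids: list[str]
    gene_of: dict[str, str]
    rna_type: dict[str, str]
    known_lnc: set[str]
    module_label: dict[str, int]
    pairs: list[tuple[str, str]]  # (lncRNA, mRNA)
    groups: list[str]


def _make_plan(config: SyntheticConfig) -> _Plan:
    rng = np.random.default_rng([config.seed, 101])
    n_total = config.n_mrna + config.n_lncrna
    tids = [f"TX{i + 1:05d}" for i in range(n_total)]
    gene_of = {t: t.replace("TX", "G") for t in tids}

    lnc_idx = rng.choice(n_total, size=config.n_lncrna, replace=False)
    rna_type = {t: "mRNA" for t in tids}
    for i in lnc_idx:
        rna_type[tids[i]] = "lncRNA"
    lncs = [t for t in tids if rna_type[t] == "lncRNA"]
    n_known = int(round(config.known_lnc_fraction * len(lncs)))
    known_lnc = set(
        np.array(lncs)[rng.choice(len(lncs), size=n_known, replace=False)]
    ) if lncs else set()

    # planted pairs go to module 1 (the trait-associated module)
    mrnas = [t for t in tids if rna_type[t] == "mRNA"]
    pair_lncs = list(rng.permutation(lncs))[: config.n_conserved_pairs]
    pair_mrnas = list(rng.permutation(mrnas))[: config.n_conserved_pairs]
    pairs = list(zip(pair_lncs, pair_mrnas))

    module_label = {t: 0 for t in tids}
    in_pairs = set(pair_lncs) | set(pair_mrnas)
    for t in in_pairs:
        module_label[t] = 1
    pool = list(rng.permutation([t for t in tids if t not in in_pairs]))
    fill = config.module_sizes[0] - len(in_pairs)
    for m, size in enumerate(config.module_sizes, start=1):
        take = fill if m == 1 else size
        for t in pool[:take]:
            module_label[t] = m
        pool = pool[take:]

    groups = [f"grp{g + 1}" for g in range(config.n_groups)]
    return _Plan(tids, gene_of, rna_type, known_lnc, module_label, pairs, groups)


# ---------------------------------------------------------------------------
# counts

def generate_counts(
    config: SyntheticConfig,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], GroundTruth]:
    """Simulate per-group count matrices sharing one merged control block.

    Returns (counts per group, sample tables per group, ground truth).
    Deterministic given ``config.seed``.
    """
    plan = _make_plan(config)
    rng = np.random.default_rng([config.seed, 202])

    n_ctrl = config.n_samples_control
    n_trt = config.n_samples_treated
    ctrl_ids = [f"CTL{j + 1:02d}" for j in range(n_ctrl)]
    trt_ids = {g: [f"{g}_T{j + 1:02d}" for j in range(n_trt)] for g in plan.groups}
    all_samples = ctrl_ids + [s for g in plan.groups for s in trt_ids[g]]
    n_samples = len(all_samples)
    treated_mask = np.array([s not in ctrl_ids for s in all_samples])

    # latent factors: one per module over all samples; the trait-module
    # factor (and, below, every sub-factor) is shifted in treated samples
    factors = rng.standard_normal((config.n_modules + 1, n_samples))
    trait_module = 1
    shift = np.where(treated_mask, config.trait_effect, 0.0)
    factors[trait_module] += shift

    tids = plan.transcript_ids
    n_genes = len(tids)
    eps = rng.standard_normal((n_genes, n_samples))
    idx_of = {t: i for i, t in enumerate(tids)}

    # Trait-module sub-structure: each planted pair anchors its own
    # sub-clique.  Sub-factor f_k mixes the module factor with a private
    # component (cor between sub-factors = pair_clique_cor); satellites
    # load sqrt(within_module_cor) on their clique's sub-factor, while
    # the pair endpoints load sqrt(within_pair_cor) — they are the hubs
    # of their clique and their mutual correlation is within_pair_cor.
    rho = config.within_module_cor
    wpc = config.within_pair_cor
    w = config.pair_clique_cor
    n_pairs = len(plan.pairs)
    clique_of = np.full(n_genes, -1)
    if n_pairs:
        # sub-factors mix the (unshifted) module factor with a private
        # component, then receive the full trait shift themselves
        sub = (
            np.sqrt(w) * (factors[trait_module] - shift)[None, :]
            + np.sqrt(1.0 - w) * rng.standard_normal((n_pairs, n_samples))
            + shift[None, :]
        )
        for k, (lnc, mrna) in enumerate(plan.pairs):
            clique_of[idx_of[lnc]] = k
            clique_of[idx_of[mrna]] = k
        satellites = [
            t for t in tids
            if plan.module_label[t] == trait_module and clique_of[idx_of[t]] < 0
        ]
        for i, t in enumerate(satellites):
            clique_of[idx_of[t]] = i % n_pairs

    labels = np.array([plan.module_label[t] for t in tids])
    pair_set = {t for p in plan.pairs for t in p}
    in_pair = np.array([t in pair_set for t in tids])
    load_sq = np.where(labels > 0, np.where(in_pair, wpc, rho), 0.0)
    gene_factor = factors[labels, :].copy()
    if n_pairs:
        in_trait = labels == trait_module
        gene_factor[in_trait] = sub[clique_of[in_trait]]
    # random loading signs keep library sizes balanced under the trait
    # shift (no composition bias) and suit the unsigned network; planted
    # pair endpoints share the positive sign
    sign = rng.choice([-1.0, 1.0], size=n_genes)
    sign[in_pair] = 1.0
    z = (
        (sign * np.sqrt(load_sq))[:, None] * gene_factor
        + np.sqrt(1.0 - load_sq)[:, None] * eps
    )

    base = np.where(
        np.array([plan.rna_type[t] for t in tids]) == "mRNA",
        config.mean_log_expr_mrna,
        config.mean_log_expr_lnc,
    ) + rng.normal(0.0, 0.4, size=n_genes)
    mu = np.exp(base[:, None] + config.log_sd * z)

    counts_all = pd.DataFrame(
        nb_counts(rng, mu, config.nb_dispersion), index=tids, columns=all_samples
    )
    counts_all.index.name = "transcript_id"

    counts, samples = {}, {}
    for g in plan.groups:
        cols = ctrl_ids + trt_ids[g]
        counts[g] = counts_all[cols].copy()
        samples[g] = pd.DataFrame(
            {
                "sample_id": cols,
                "group": g,
                "trait": [0] * n_ctrl + [1] * n_trt,
            }
        )

    truth = GroundTruth(
        rna_type=dict(plan.rna_type),
        expected_class=_expected_classes(plan),
        module_label=dict(plan.module_label),
        trait_modules={g: trait_module for g in plan.groups},
        conserved_pairs=list(plan.pairs),
        gene_of=dict(plan.gene_of),
        planted_set_name="planted_set",
        groups=list(plan.groups),
    )
    return counts, samples, truth


def _expected_classes(plan: _Plan) -> dict[str, str]:
    out = {}
    for t in plan.transcript_ids:
        if plan.rna_type[t] == "mRNA":
            out[t] = TranscriptClass.KNOWN_MRNA.value
        elif t in plan.known_lnc:
            out[t] = TranscriptClass.KNOWN_LNCRNA.value
        else:
            out[t] = TranscriptClass.NOVEL_LNCRNA.value
    return out


# ---------------------------------------------------------------------------
# sequences and records

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def _coding_seq(rng: np.random.Generator, total_len: int, orf_aa: int) -> str:
    """Random sequence with a planted ATG-initiated ORF of >= orf_aa codons."""
    orf = "ATG" + "".join(
        _NON_STOP_CODONS[i]
        for i in rng.integers(0, len(_NON_STOP_CODONS), size=orf_aa - 1)
    ) + "TAA"
    total_len = max(total_len, len(orf) + 6)
    pos = int(rng.integers(0, total_len - len(orf) + 1))
    return _random_seq(rng, pos) + orf + _random_seq(rng, total_len - pos - len(orf))


def _noncoding_seq(rng: np.random.Generator, total_len: int) -> str:
    """Random sequence ablated until its longest ORF is < 100 aa."""
    seq = _random_seq(rng, total_len)
    for _ in range(200):
        best, _frame, start = _scan_forward_frames(seq)
        if best < MAX_NONCODING_ORF_AA:
            return seq
        cut = start + 3 * (MAX_NONCODING_ORF_AA // 2)  # in-frame, mid-ORF
        seq = seq[:cut] + "TAA" + seq[cut + 3 :]
    raise RuntimeError("ORF ablation did not converge")  # pragma: no cover


_KNOWN_LNC_BIOTYPES = ("lincRNA", "antisense", "processed_transcript", "non_coding")

# decoy archetypes cycled to exercise every discard branch of the cascade
_DECOY_KINDS = ("short", "orf", "db_hit", "cpc", "pfam")


def generate_transcript_records(config: SyntheticConfig) -> list[TranscriptRecord]:
    """Build TranscriptRecords consistent with the counts' ground truth.

    mRNAs carry a protein-coding biotype and a planted ORF >= 100 aa;
    lncRNAs are > 200 nt with longest ORF < 100 aa, split between known
    biotypes and novel (no biotype, no evidence).  ``config.n_decoys``
    extra records (ids DX*) cycle through the discard archetypes.
    """
    plan = _make_plan(config)
    rng = np.random.default_rng([config.seed, 303])
    records = []
    for t in plan.transcript_ids:
        if plan.rna_type[t] == "mRNA":
            orf_aa = int(rng.integers(100, 350))
            length = max(int(rng.lognormal(np.log(1800), 0.35)), orf_aa * 3 + 60)
            records.append(
                TranscriptRecord(
                    transcript_id=t,
                    gene_id=plan.gene_of[t],
                    sequence=_coding_seq(rng, length, orf_aa),
                    exon_count=int(rng.integers(3, 16)),
                    known_biotype="protein_coding",
                )
            )
        else:
            length = max(int(rng.lognormal(np.log(650), 0.4)), 250)
            biotype = None
            if t in plan.known_lnc:
                biotype = _KNOWN_LNC_BIOTYPES[int(rng.integers(0, 4))]
            records.append(
                TranscriptRecord(
                    transcript_id=t,
                    gene_id=plan.gene_of[t],
                    sequence=_noncoding_seq(rng, length),
                    exon_count=int(rng.integers(1, 5)),
                    known_biotype=biotype,
                )
            )
    for d in range(config.n_decoys):
        kind = _DECOY_KINDS[d % len(_DECOY_KINDS)]
        tid = f"DX{d + 1:04d}"
        gene = tid.replace("DX", "GD")
        if kind == "short":
            rec = TranscriptRecord(tid, gene, sequence=_noncoding_seq(rng, 150))
        elif kind == "orf":
            rec = TranscriptRecord(
                tid, gene, sequence=_coding_seq(rng, 700, int(rng.integers(100, 200)))
            )
        elif kind == "db_hit":
            rec = TranscriptRecord(
                tid, gene, sequence=_random_seq(rng, 800),
                evidence=CodingEvidence(protein_db_hit=True),
            )
        elif kind == "cpc":
            rec = TranscriptRecord(
                tid, gene, sequence=_noncoding_seq(rng, 500),
                evidence=CodingEvidence(cpc_coding=True),
            )
        else:  # pfam
            rec = TranscriptRecord(
                tid, gene, sequence=_noncoding_seq(rng, 500),
                evidence=CodingEvidence(pfam_hit=True),
            )
        records.append(rec)
    return records


def expected_decoy_class(record: TranscriptRecord) -> str:
    """Expected catalog class for a decoy record, by its construction."""
    if record.evidence.protein_db_hit:
        return TranscriptClass.CODING_DISCARD.value
    if record.length_nt <= 200:
        return TranscriptClass.SHORT_DISCARD.value
    from .catalog import longest_orf_length

    if longest_orf_length(record.sequence) >= MAX_NONCODING_ORF_AA:
        return TranscriptClass.ORF_DISCARD.value
    if record.evidence.cpc_coding or record.evidence.pfam_hit:
        return TranscriptClass.CODING_DISCARD.value
    return TranscriptClass.NOVEL_LNCRNA.value


# ---------------------------------------------------------------------------
# gene sets

def generate_gene_sets(
    config: SyntheticConfig,
    truth: GroundTruth,
    n_decoy_sets: int = 15,
    planted_in_fraction: float = 0.85,
    decoy_size_range: tuple[int, int] = (10, 40),
) -> GeneSetCollection:
    """One planted set drawn mostly from the trait module plus decoys.

    The planted set always contains the mRNA genes of the planted
    conserved pairs; decoy sets are uniform draws from the background.
    """
    universe = {truth.gene_of[t] for t in truth.gene_of if t.startswith("TX")}
    if not universe:
        raise ConfigError("empty background universe")
    rng = np.random.default_rng([config.seed, 404])

    trait_mod = truth.trait_modules[truth.groups[0]]
    module_mrna_genes = sorted(
        truth.gene_of[t]
        for t, m in truth.module_label.items()
        if m == trait_mod and truth.rna_type[t] == "mRNA"
    )
    pair_genes = {truth.gene_of[m] for _l, m in truth.conserved_pairs}
    n_in = max(len(pair_genes), int(round(0.8 * len(module_mrna_genes))))
    in_members = set(pair_genes)
    extra = [g for g in module_mrna_genes if g not in in_members]
    need = n_in - len(in_members)
    if need > 0 and extra:
        take = rng.choice(len(extra), size=min(need, len(extra)), replace=False)
        in_members |= {extra[i] for i in take}
    n_out = max(1, int(round(len(in_members) * (1 - planted_in_fraction)
                             / planted_in_fraction)))
    background = sorted(universe - in_members)
    out_members = set()
    if background:
        take = rng.choice(len(background), size=min(n_out, len(background)),
                          replace=False)
        out_members = {background[i] for i in take}

    sets = {truth.planted_set_name: in_members | out_members}
    pool = sorted(universe)
    lo, hi = decoy_size_range
    for d in range(n_decoy_sets):
        size = int(rng.integers(lo, hi))
        take = rng.choice(len(pool), size=min(size, len(pool)), replace=False)
        sets[f"decoy_{d + 1:02d}"] = {pool[i] for i in take}
    return GeneSetCollection(sets=sets, universe=set(universe))


# ---------------------------------------------------------------------------
# full dataset + on-disk layout

def generate_dataset(config: SyntheticConfig) -> Dataset:
    counts, samples, truth = generate_counts(config)
    records = generate_transcript_records(config)
    gene_sets = generate_gene_sets(config, truth)
    return Dataset(config, counts, samples, records, truth, gene_sets)


def write_dataset(dataset: Dataset, outdir: str | Path) -> None:
    """Write the full text layout consumed by the analysis CLIs.

    counts_<group>.tsv, samples_<group>.tsv, transcripts.fasta,
    annotation.gtf, evidence.tsv, genesets.gmt, background_genes.txt,
    truth.json, config.json, groups.txt.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for g in dataset.truth.groups:
        io.write_counts(dataset.counts[g], out / f"counts_{g}.tsv")
        io.write_samples(dataset.samples[g], out / f"samples_{g}.tsv")
    io.write_fasta(
        {r.transcript_id: r.sequence for r in dataset.records},
        out / "transcripts.fasta",
    )
    io.write_gtf(_gtf_rows(dataset.records), out / "annotation.gtf")
    _write_evidence(dataset.records, out / "evidence.tsv")
    io.write_gmt(dataset.gene_sets.sets, out / "genesets.gmt")
    io.write_gene_list(dataset.gene_sets.universe, out / "background_genes.txt")
    dataset.truth.to_json(out / "truth.json")
    with open(out / "config.json", "w") as fh:
        json.dump(dataset.config.to_dict(), fh, indent=1)
    with open(out / "groups.txt", "w") as fh:
        fh.write("\n".join(dataset.truth.groups) + "\n")


def _gtf_rows(records: Sequence[TranscriptRecord]):
    pos = 1
    for rec in records:
        attrs = f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}";'
        if rec.known_biotype:
            attrs += f' transcript_biotype "{rec.known_biotype}";'
        end = pos + rec.length_nt - 1 + 100 * (rec.exon_count - 1)
        yield ("chr1", "lncnet", "transcript", pos, end, ".", "+", ".", attrs)
        exon_lens = np.full(rec.exon_count, rec.length_nt // rec.exon_count)
        exon_lens[: rec.length_nt % rec.exon_count] += 1
        estart = pos
        for elen in exon_lens:
            yield ("chr1", "lncnet", "exon", estart, estart + int(elen) - 1,
                   ".", "+", ".", attrs)
            estart += int(elen) + 100
        pos = end + 1000


def _write_evidence(records: Sequence[TranscriptRecord], path: Path) -> None:
    rows = [
        (r.transcript_id, int(r.evidence.protein_db_hit),
         int(r.evidence.cpc_coding), int(r.evidence.pfam_hit))
        for r in records
        if r.evidence.protein_db_hit or r.evidence.cpc_coding or r.evidence.pfam_hit
    ]
    pd.DataFrame(
        rows, columns=["transcript_id", "protein_db_hit", "cpc_coding", "pfam_hit"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# hub-structured expression for soft-threshold checks

def scale_free_expression(
    n_genes: int = 600, n_samples: int = 30, n_hubs: int = 12, seed: int = 11
) -> pd.DataFrame:
    """Expression whose co-expression connectivity is approximately
    scale-free: genes attach preferentially to a few hub profiles with
    variable coupling strength, yielding a heavy-tailed connectivity
    distribution suitable for soft-threshold selection tests.
    """
    rng = np.random.default_rng(seed)
    hubs = rng.standard_normal((n_hubs, n_samples))
    attach_counts = np.ones(n_hubs)
    X = np.empty((n_genes, n_samples))
    for i in range(n_genes):
        probs = attach_counts / attach_counts.sum()
        h = rng.choice(n_hubs, p=probs)
        attach_counts[h] += 1.0
        w = rng.uniform(0.3, 0.95)
        X[i] = w * hubs[h] + np.sqrt(1 - w * w) * rng.standard_normal(n_samples)
    ids = [f"TX{i + 1:05d}" for i in range(n_genes)]
    cols = [f"S{j + 1:02d}" for j in range(n_samples)]
    return pd.DataFrame(X, index=ids, columns=cols)
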