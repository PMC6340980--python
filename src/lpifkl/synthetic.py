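"""Seeded generator of complete toy lncRNA–protein datasets.

The generator plants a shared block structure across every modality: each
lncRNA and each protein belongs to one of ``k_blocks`` latent groups, block-g
lncRNAs preferentially interact with block-g proteins, sequences are mutated
copies of block motifs, expression profiles scatter around block means, and
GO term sets are drawn from block-specific pools. Every kernel therefore
carries (noisy) signal about the same latent structure, so full-pipeline
recovery is testable offline with no external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import (
    ExpressionProfile,
    GOAnnotation,
    InteractionMatrix,
    MoleculeRegistry,
    SequenceRecord,
    load_expression,
    load_fasta,
    load_go,
)
from .pipeline import LPIDataset

RNA_LETTERS = "ACGU"
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

MODALITIES = ("expression", "go", "lnc_seq", "pro_seq")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-block generator (defaults are the reference
    study conditions used throughout the test suite)."""

    m: int = 200
    n: int = 30
    k_blocks: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    seq_len_range: tuple[int, int] = (60, 120)
    expr_dim: int = 24
    go_pool: int = 8
    go_shared: int = 4
    noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.k_blocks > min(self.m, self.n):
            raise ValueError("k_blocks must not exceed min(m, n)")
        if self.expr_dim < 1:
            raise ValueError("expr_dim must be >= 1")
        if self.seq_len_range[0] < 3 or self.seq_len_range[0] > self.seq_len_range[1]:
            raise ValueError("seq_len_range must satisfy 3 <= lo <= hi")
        if not (0 <= self.noise <= 1):
            raise ValueError("noise must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground-truth block assignments."""

    data: LPIDataset
    lnc_blocks: dict[str, int]
    pro_blocks: dict[str, int]
    spec: SyntheticSpec

    @property
    def interactions(self) -> InteractionMatrix:
        return self.data.interactions


def _balanced_blocks(count: int, k: int, rng: np.random.Generator) -> np.ndarray:
    base = np.arange(count) % k
    return rng.permutation(base)


def _mutate(template: str, letters: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(template)
    for h in range(len(chars)):
        if rng.random() < rate:
            chars[h] = letters[rng.integers(len(letters))]
    return "".join(chars)


def generate(spec: SyntheticSpec = SyntheticSpec()) -> SyntheticDataset:
    """Draw a complete dataset; fully determined by ``spec`` (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    k = spec.k_blocks

    lnc_ids = tuple(f"lnc{i:04d}" for i in range(spec.m))
    pro_ids = tuple(f"pro{j:03d}" for j in range(spec.n))
    registry = MoleculeRegistry(lnc_ids, pro_ids)

    lnc_block = _balanced_blocks(spec.m, k, rng)
    pro_block = _balanced_blocks(spec.n, k, rng)

    prob = np.where(
        lnc_block[:, None] == pro_block[None, :], spec.p_in, spec.p_out
    )
    F = (rng.random((spec.m, spec.n)) < prob).astype(float)
    interactions = InteractionMatrix(F, registry)

    lo, hi = spec.seq_len_range
    lnc_templates = [
        "".join(RNA_LETTERS[i] for i in rng.integers(4, size=rng.integers(lo, hi + 1)))
        for _ in range(k)
    ]
    pro_templates = [
        "".join(AA_LETTERS[i] for i in rng.integers(20, size=rng.integers(lo, hi + 1)))
        for _ in range(k)
    ]
    lnc_seqs = [
        SequenceRecord(lnc_ids[i], _mutate(lnc_templates[lnc_block[i]], RNA_LETTERS, spec.noise, rng))
        for i in range(spec.m)
    ]
    pro_seqs = [
        SequenceRecord(pro_ids[j], _mutate(pro_templates[pro_block[j]], AA_LETTERS, spec.noise, rng))
        for j in range(spec.n)
    ]

    block_means = rng.normal(0.0, 1.0, size=(k, spec.expr_dim))
    expression = [
        ExpressionProfile(
            lnc_ids[i],
            tuple(
                float(v)
                for v in block_means[lnc_block[i]]
                + rng.normal(0.0, spec.noise + 0.01, spec.expr_dim)
            ),
        )
        for i in range(spec.m)
    ]

    pools = [[f"GO:{g:02d}{t:02d}" for t in range(spec.go_pool)] for g in range(k)]
    shared = [f"GO:SH{t:02d}" for t in range(spec.go_shared)]
    go = []
    for j in range(spec.n):
        g = pro_block[j]
        terms = {t for t in pools[g] if rng.random() < 0.6}
        terms |= {t for t in shared if rng.random() < 0.5}
        for other in range(k):
            if other != g:
                terms |= {t for t in pools[other] if rng.random() < spec.noise}
        if not terms:  # guarantee an annotated protein
            terms = {pools[g][int(rng.integers(spec.go_pool))]}
        go.append(GOAnnotation(pro_ids[j], frozenset(terms)))

    data = LPIDataset(interactions, lnc_seqs, pro_seqs, expression, go)
    return SyntheticDataset(
        data,
        {lnc_ids[i]: int(lnc_block[i]) for i in range(spec.m)},
        {pro_ids[j]: int(pro_block[j]) for j in range(spec.n)},
        spec,
    )


def export(dataset: SyntheticDataset, directory) -> None:
    """Write the five standard input files plus the truth table.

    Files: interactions.tsv, lnc.fasta, pro.fasta, expression.tsv, go.tsv,
    truth.tsv (molecule id, kind, block). The truth file doubles as the
    explicit id list, so a reload reconstructs the registry exactly even when
    a molecule has no interactions.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    data = dataset.data
    reg = data.registry

    with open(d / "interactions.tsv", "w") as fh:
        for i, j in data.interactions.positive_pairs():
            fh.write(f"{reg.lnc_ids[i]}\t{reg.pro_ids[j]}\n")
    for name, seqs in (("lnc.fasta", data.lnc_seqs), ("pro.fasta", data.pro_seqs)):
        with open(d / name, "w") as fh:
            for rec in seqs:
                fh.write(f">{rec.id}\n{rec.residues}\n")
    with open(d / "expression.tsv", "w") as fh:
        for prof in data.expression:
            fh.write(prof.id + "\t" + "\t".join(repr(v) for v in prof.vector) + "\n")
    with open(d / "go.tsv", "w") as fh:
        for ann in data.go:
            for term in sorted(ann.terms):
                fh.write(f"{ann.id}\t{term}\n")
    with open(d / "truth.tsv", "w") as fh:
        for lid, b in dataset.lnc_blocks.items():
            fh.write(f"{lid}\tlnc\t{b}\n")
        for pid, b in dataset.pro_blocks.items():
            fh.write(f"{pid}\tpro\t{b}\n")


def load_exported(directory) -> LPIDataset:
    """Reload a directory written by :func:`export` (registry from truth.tsv)."""
    from .data_io import load_interactions

    d = Path(directory)
    lnc_ids, pro_ids = [], []
    with open(d / "truth.tsv") as fh:
        for line in fh:
            mol, kind, _ = line.rstrip("\n").split("\t")
            (lnc_ids if kind == "lnc" else pro_ids).append(mol)
    registry = MoleculeRegistry(tuple(lnc_ids), tuple(pro_ids))
    interactions, _ = load_interactions(
        d / "interactions.tsv", registry_mode="strict", registry=registry
    )
    lnc_seqs, _ = load_fasta(d / "lnc.fasta", "rna")
    pro_seqs, _ = load_fasta(d / "pro.fasta", "protein")
    expression = load_expression(d / "expression.tsv")
    go = load_go(d / "go.tsv")
    return LPIDataset(interactions, lnc_seqs, pro_seqs, expression, go)


def degrade(
    dataset: SyntheticDataset, drop_modality: str, fraction: float, seed: int = 0
) -> SyntheticDataset:
    """Remove one modality's records for a seeded random subset of molecules."""
    if drop_modality not in MODALITIES:
        raise ValueError(f"unknown modality {drop_modality!r}; choose from {MODALITIES}")
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    data = dataset.data

    def keep(ids: list[str]) -> set[str]:
        drop_n = int(round(fraction * len(ids)))
        dropped = set(rng.choice(ids, size=drop_n, replace=False).tolist())
        return {x for x in ids if x not in dropped}

    new = LPIDataset(
        data.interactions,
        data.lnc_seqs,
        data.pro_seqs,
        data.expression,
        data.go,
        data.pssms,
    )
    if drop_modality == "expression":
        kept = keep([p.id for p in data.expression])
        new.expression = [p for p in data.expression if p.id in kept]
    elif drop_modality == "go":
        kept = keep([a.id for a in data.go])
        new.go = [a for a in data.go if a.id in kept]
    elif drop_modality == "lnc_seq":
        kept = keep([r.id for r in data.lnc_seqs])
        new.lnc_seqs = [r for r in data.lnc_seqs if r.id in kept]
    elif drop_modality == "pro_seq":
        kept = keep([r.id for r in data.pro_seqs])
        new.pro_seqs = [r for r in data.pro_seqs if r.id in kept]
    return SyntheticDataset(new, dataset.lnc_blocks, dataset.pro_blocks, dataset.spec)
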