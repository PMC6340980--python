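"""Input/output for interaction networks, sequences, expression, GO and PSSM data.

The central objects are :class:`MoleculeRegistry`, which fixes the ordering of
lncRNA and protein identifiers for every downstream matrix axis, and
:class:`InteractionMatrix`, the m-by-n binary adjacency with an optional mask
that hides held-out pairs from every training computation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
RNA_WILDCARD = "N"
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_WILDCARD = "X"

# Column order of a PSI-BLAST ASCII profile and of every PSSM matrix here.
PSSM_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class MoleculeRegistry:
    """Ordered identifier lists for the lncRNA set L (size m) and protein set P (size n).

    The ordering is fixed at load time; row i of every lncRNA-axis matrix and
    column j of every protein-axis matrix refer to ``lnc_ids[i]`` / ``pro_ids[j]``.
    """

    lnc_ids: tuple[str, ...]
    pro_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.lnc_ids)) != len(self.lnc_ids):
            raise ValueError("duplicate lncRNA identifiers in registry")
        if len(set(self.pro_ids)) != len(self.pro_ids):
            raise ValueError("duplicate protein identifiers in registry")
        if len(self.lnc_ids) < 2 or len(self.pro_ids) < 2:
            raise ValueError("registry needs at least 2 lncRNAs and 2 proteins")

    @property
    def m(self) -> int:
        return len(self.lnc_ids)

    @property
    def n(self) -> int:
        return len(self.pro_ids)

    def lnc_index(self, lnc_id: str) -> int:
        return self.lnc_ids.index(lnc_id)

    def pro_index(self, pro_id: str) -> int:
        return self.pro_ids.index(pro_id)


@dataclass
class InteractionMatrix:
    """Binary adjacency F over (lncRNA, protein) pairs with a maskable training view.

    ``values[i, j] == 1`` iff lncRNA i is known to interact with protein j.
    ``mask`` is a set of (row, col) positions hidden for evaluation: the
    training view returned by :meth:`train_view` reads them as 0 regardless of
    the hidden value, so no kernel or model quantity can leak held-out labels.
    """

    values: np.ndarray
    registry: MoleculeRegistry
    mask: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.registry.m, self.registry.n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match registry "
                f"({self.registry.m}, {self.registry.n})"
            )
        unmasked = np.ones_like(self.values, dtype=bool)
        for i, j in self.mask:
            unmasked[i, j] = False
        vals = self.values[unmasked]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("unmasked interaction entries must be exactly 0 or 1")

    def train_view(self) -> np.ndarray:
        """Dense float copy of F with masked positions forced to 0."""
        out = self.values.copy()
        for i, j in self.mask:
            out[i, j] = 0.0
        return out

    def with_mask(self, pairs) -> "InteractionMatrix":
        """Return a copy whose mask is exactly ``pairs``."""
        return InteractionMatrix(self.values.copy(), self.registry, frozenset(pairs))

    def positive_pairs(self) -> list[tuple[int, int]]:
        rows, cols = np.nonzero(self.values == 1.0)
        return list(zip(rows.tolist(), cols.tolist()))


@dataclass(frozen=True)
class SequenceRecord:
    """A molecule's residue string over the RNA alphabet {A,C,G,U} plus N, or the
    20-letter amino-acid alphabet plus X."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for {self.id!r}")


@dataclass(frozen=True)
class ExpressionProfile:
    id: str
    vector: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.vector).all():
            raise ValueError(f"non-finite expression values for {self.id!r}")


@dataclass(frozen=True)
class GOAnnotation:
    id: str
    terms: frozenset[str]


@dataclass(frozen=True)
class PSSMProfile:
    """Position-specific score matrix: one row per residue, 20 columns in
    :data:`PSSM_AA_ORDER`."""

    id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(f"PSSM for {self.id!r} must have 20 columns")


@dataclass
class LoadReport:
    """Per-file accounting of lossy normalisations applied at load time."""

    wildcard_substitutions: int = 0
    duplicate_pairs: int = 0


def load_interactions(
    path, registry_mode: str = "build", registry: MoleculeRegistry | None = None
) -> tuple[InteractionMatrix, MoleculeRegistry]:
    """Read a two-column TSV of positive (lncRNA, protein) pairs.

    In ``build`` mode the registry is created in first-appearance order; in
    ``strict`` mode every identifier must already exist in ``registry``.
    Duplicate pairs collapse to a single 1 with a warning.
    """
    if registry_mode not in ("build", "strict"):
        raise ValueError(f"unknown registry_mode {registry_mode!r}")
    if registry_mode == "strict" and registry is None:
        raise ValueError("strict mode requires an existing registry")

    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ParseError(f"{path}:{lineno}: expected two tab-separated ids")
            pair = (fields[0], fields[1])
            if pair in seen:
                n_dup += 1
                continue
            seen.add(pair)
            pairs.append(pair)
    if n_dup:
        warnings.warn(f"{path}: {n_dup} duplicate interaction pair(s) collapsed")

    if registry_mode == "build":
        lnc_ids: list[str] = []
        pro_ids: list[str] = []
        for lnc, pro in pairs:
            if lnc not in lnc_ids:
                lnc_ids.append(lnc)
            if pro not in pro_ids:
                pro_ids.append(pro)
        registry = MoleculeRegistry(tuple(lnc_ids), tuple(pro_ids))
    else:
        assert registry is not None
        known_l, known_p = set(registry.lnc_ids), set(registry.pro_ids)
        for lnc, pro in pairs:
            if lnc not in known_l:
                raise ParseError(f"unknown lncRNA id {lnc!r} in strict mode")
            if pro not in known_p:
                raise ParseError(f"unknown protein id {pro!r} in strict mode")

    values = np.zeros((registry.m, registry.n))
    l_idx = {x: i for i, x in enumerate(registry.lnc_ids)}
    p_idx = {x: j for j, x in enumerate(registry.pro_ids)}
    for lnc, pro in pairs:
        values[l_idx[lnc], p_idx[pro]] = 1.0
    return InteractionMatrix(values, registry), registry


def load_fasta(path, alphabet: str) -> tuple[list[SequenceRecord], LoadReport]:
    """Read FASTA records; RNA gets T→U mapping, off-alphabet characters become
    the alphabet's wildcard and are counted in the returned :class:`LoadReport`."""
    if alphabet not in ("rna", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = RNA_ALPHABET if alphabet == "rna" else PROTEIN_ALPHABET
    wildcard = RNA_WILDCARD if alphabet == "rna" else PROTEIN_WILDCARD

    report = LoadReport()
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "rna":
            seq = seq.replace("T", "U")
        cleaned = []
        for ch in seq:
            if ch in allowed or ch == wildcard:
                cleaned.append(ch)
            else:
                cleaned.append(wildcard)
                report.wildcard_substitutions += 1
        if not cleaned:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(rec.id, "".join(cleaned)))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records, report


def load_expression(path) -> list[ExpressionProfile]:
    """Read a TSV/CSV table: first column lncRNA id, remaining columns numeric."""
    sep = "," if str(path).endswith(".csv") else "\t"
    profiles: list[ExpressionProfile] = []
    dim: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(sep)
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected id plus numeric columns")
            vals = []
            for col, cell in enumerate(fields[1:], start=2):
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: column {col}: non-numeric value {cell!r}"
                    ) from None
            if not np.isfinite(vals).all():
                raise ParseError(f"{path}:{lineno}: non-finite expression value")
            if dim is None:
                dim = len(vals)
            elif len(vals) != dim:
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(vals)} values, expected {dim})"
                )
            profiles.append(ExpressionProfile(fields[0], tuple(vals)))
    if not profiles:
        raise ParseError(f"{path}: empty expression table")
    return profiles


def load_go(path) -> list[GOAnnotation]:
    """Read a two-column TSV of (protein id, GO term id); terms grouped into sets."""
    terms: dict[str, set[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ParseError(f"{path}:{lineno}: expected (protein id, GO term)")
            pid, term = fields
            if pid not in terms:
                terms[pid] = set()
                order.append(pid)
            terms[pid].add(term)
    return [GOAnnotation(pid, frozenset(terms[pid])) for pid in order]


def load_pssm(path, protein_id: str | None = None) -> PSSMProfile:
    """Read one PSI-BLAST ASCII PSSM file (the classic ``-Q`` output dialect).

    Data lines start with a position index and residue, followed by 20 (or 40)
    integer columns; only the first 20 (log-odds) are kept.
    """
    path = Path(path)
    pid = protein_id if protein_id is not None else path.stem
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if len(fields) < 22:
                continue
            if not fields[0].isdigit() or len(fields[1]) != 1:
                continue
            try:
                rows.append([float(x) for x in fields[2:22]])
            except ValueError:
                continue
    if not rows:
        raise ParseError(f"{path}: no PSSM score rows found")
    return PSSMProfile(pid, np.array(rows))


def load_pssm_dir(directory) -> dict[str, PSSMProfile]:
    """Load every PSSM file in a directory; filename stem is the protein id."""
    out: dict[str, PSSMProfile] = {}
    for path in sorted(Path(directory).iterdir()):
        if path.is_file():
            out[path.stem] = load_pssm(path)
    return out


def write_scores(values: np.ndarray, registry: MoleculeRegistry, path) -> None:
    """Write an m×n score matrix as TSV: lncRNA rows, protein columns, full
    ``repr`` float precision so a read-back reproduces the text exactly."""
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("refusing to write an empty score matrix")
    if values.shape != (registry.m, registry.n):
        raise ValueError("score matrix shape does not match registry")
    with open(path, "w") as fh:
        fh.write("lncRNA\t" + "\t".join(registry.pro_ids) + "\n")
        for i, lnc in enumerate(registry.lnc_ids):
            fh.write(lnc + "\t" + "\t".join(repr(float(v)) for v in values[i]) + "\n")


def read_scores(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Inverse of :func:`write_scores`: returns (matrix, lnc_ids, pro_ids)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        pro_ids = header[1:]
        lnc_ids: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            lnc_ids.append(fields[0])
            rows.append([float(x) for x in fields[1:]])
    return np.array(rows), lnc_ids, pro_ids
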