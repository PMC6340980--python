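"""Similarity kernels for the lncRNA and protein spaces.

Four kernels per space enter the fusion step:

==========  =====================================  =====================================
name        lncRNA space                           protein space
==========  =====================================  =====================================
``GIP``     Gaussian interaction profile over      same, over columns of F_train
            rows of the (masked) adjacency
``SW``      normalised Smith–Waterman score        same, BLOSUM62 scoring
``SF``      RBF over conjoint-triad 3-mer          RBF over Pse-PSSM features
            frequencies
``EXP``     RBF over expression profiles           —
``GO``      —                                      Jaccard index of GO term sets
==========  =====================================  =====================================

The GIP and RBF kernels are positive semidefinite by construction; the
normalised alignment and Jaccard matrices are not guaranteed PSD and pass
through :func:`psd_repair` (eigenvalue clipping) before cosine normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .data_io import (
    PSSM_AA_ORDER,
    ExpressionProfile,
    GOAnnotation,
    InteractionMatrix,
    PSSMProfile,
    SequenceRecord,
)

SYMMETRY_TOL = 1e-10


@dataclass
class KernelMatrix:
    """A named square similarity matrix over one molecular space."""

    values: np.ndarray
    axis_ids: tuple[str, ...]
    name: str
    space: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.axis_ids)
        if self.values.shape != (p, p):
            raise ValueError("kernel shape does not match axis ids")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-8:
            raise ValueError(f"kernel {self.name!r} is not symmetric")
        self.values = 0.5 * (self.values + self.values.T)


@dataclass(frozen=True)
class GIPParams:
    """Bandwidths for the Gaussian interaction profile kernel.

    ``normalize_sigma`` divides the bandwidth by the mean squared profile norm
    (the conventional variant); the default keeps the raw sigma.
    """

    sigma_lnc: float = 1.0
    sigma_pro: float = 1.0
    normalize_sigma: bool = False

    def __post_init__(self) -> None:
        if self.sigma_lnc <= 0 or self.sigma_pro <= 0:
            raise ValueError("GIP bandwidth must be positive")


@dataclass(frozen=True)
class FeatureVector:
    id: str
    vector: tuple[float, ...]


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution scores and affine gap penalties for local alignment.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
    """

    alphabet: str  # "rna" or "protein"
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def substitution_matrix(self):
        if self.alphabet == "protein":
            return substitution_matrices.load("BLOSUM62")
        letters = "ACGUN"
        data = np.full((5, 5), self.mismatch)
        for i in range(4):  # N never matches, not even itself
            data[i, i] = self.match
        return substitution_matrices.Array(alphabet=letters, dims=2, data=data)


def _squared_distances(X: np.ndarray) -> np.ndarray:
    sq = (X * X).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def gip_kernel(
    F_train: InteractionMatrix | np.ndarray,
    space: str,
    params: GIPParams = GIPParams(),
    axis_ids: tuple[str, ...] | None = None,
) -> KernelMatrix:
    """Gaussian interaction profile kernel K(a,b) = exp(-sigma * ||F_a - F_b||^2).

    Profiles are rows (lncRNA space) or columns (protein space) of the masked
    training adjacency; held-out entries never influence the result because
    only the training view is read.
    """
    if isinstance(F_train, InteractionMatrix):
        mat = F_train.train_view()
        ids = F_train.registry.lnc_ids if space == "lnc" else F_train.registry.pro_ids
    else:
        mat = np.asarray(F_train, dtype=float)
        ids = axis_ids if axis_ids is not None else tuple(
            f"{space}{i}" for i in range(mat.shape[0 if space == 'lnc' else 1])
        )
    if space == "lnc":
        profiles, sigma = mat, params.sigma_lnc
    elif space == "pro":
        profiles, sigma = mat.T, params.sigma_pro
    else:
        raise ValueError(f"unknown space {space!r}")
    if params.normalize_sigma:
        mean_sq = float((profiles * profiles).sum(axis=1).mean())
        sigma = sigma / mean_sq if mean_sq > 0 else sigma
    K = np.exp(-sigma * _squared_distances(profiles))
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, tuple(ids), "GIP", space)


def sw_scores(records: list[SequenceRecord], scoring: AlignmentScoring) -> np.ndarray:
    """Raw Smith–Waterman local alignment scores for all pairs (incl. self)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = scoring.substitution_matrix()
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    p = len(records)
    S = np.zeros((p, p))
    for a in range(p):
        for b in range(a, p):
            S[a, b] = S[b, a] = aligner.score(records[a].residues, records[b].residues)
    return S


def sw_kernel(
    records: list[SequenceRecord], scoring: AlignmentScoring, space: str = "lnc"
) -> KernelMatrix:
    """Normalised Smith–Waterman kernel K(a,b) = SW(a,b)/sqrt(SW(a,a) SW(b,b))."""
    S = sw_scores(records, scoring)
    self_scores = np.diag(S)
    bad = np.nonzero(self_scores <= 0)[0]
    if bad.size:
        raise ValueError(
            f"zero Smith-Waterman self-score for {records[bad[0]].id!r}"
        )
    denom = np.sqrt(np.outer(self_scores, self_scores))
    K = S / denom
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, tuple(r.id for r in records), "SW", space)


_RNA_TRIPLETS = {
    a + b + c: i
    for i, (a, b, c) in enumerate(
        (a, b, c) for a in "ACGU" for b in "ACGU" for c in "ACGU"
    )
}


def _l2_normalize(v: np.ndarray) -> np.ndarray:
    norm = float(np.linalg.norm(v))
    return v / norm if norm > 0 else v


def ct_features(records: list[SequenceRecord]) -> list[FeatureVector]:
    """Conjoint-triad descriptor for RNA: 64 overlapping 3-mer frequencies.

    Counts are divided by the number of windows (d - 2); windows containing a
    wildcard are skipped. The vector is then L2-normalised (zero stays zero).
    """
    out = []
    for rec in records:
        v = np.zeros(64)
        d = len(rec.residues)
        if d >= 3:
            for h in range(d - 2):
                idx = _RNA_TRIPLETS.get(rec.residues[h : h + 3])
                if idx is not None:
                    v[idx] += 1.0
            v /= d - 2
        out.append(FeatureVector(rec.id, tuple(_l2_normalize(v))))
    return out


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def surrogate_pssm(record: SequenceRecord) -> PSSMProfile:
    """Sequence-only stand-in profile: position h's 20 scores are the BLOSUM62
    row of residue h (X rows for wildcards). Synthetic by construction — used
    when no alignment-derived PSSM file is supplied."""
    rows = np.empty((len(record.residues), 20))
    for h, ch in enumerate(record.residues):
        ch = ch if ch in _BLOSUM62.alphabet else "X"
        rows[h] = [_BLOSUM62[ch, aa] for aa in PSSM_AA_ORDER]
    return PSSMProfile(record.id, rows)


def psepssm_features(
    records: list[SequenceRecord],
    pssms: dict[str, PSSMProfile] | None = None,
    lag: int = 1,
) -> list[FeatureVector]:
    """Pse-PSSM descriptor: 20 standardised column means plus, for each lag
    1..xi, 20 mean squared differences between scores at positions h and h+xi.

    Each PSSM column is standardised across positions (mean 0, sd 1; constant
    columns become zero). With lag=1 the vector has 40 entries; the general
    length is 20*(1+lag). L2-normalised at the end.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    pssms = pssms or {}
    out = []
    for rec in records:
        profile = pssms.get(rec.id)
        if profile is None:
            profile = surrogate_pssm(rec)
        M = profile.scores
        if M.shape[0] != len(rec.residues):
            raise ValueError(
                f"PSSM for {rec.id!r} has {M.shape[0]} rows but the sequence "
                f"has {len(rec.residues)} residues"
            )
        mu = M.mean(axis=0)
        sd = M.std(axis=0)
        Z = np.where(sd > 0, (M - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        parts = [Z.mean(axis=0)]
        d = Z.shape[0]
        for xi in range(1, lag + 1):
            if d > xi:
                diff = Z[:-xi] - Z[xi:]
                parts.append((diff * diff).mean(axis=0))
            else:
                parts.append(np.zeros(20))
        v = _l2_normalize(np.concatenate(parts))
        out.append(FeatureVector(rec.id, tuple(v)))
    return out


def rbf_kernel(
    features: list[FeatureVector], gamma: float = 1.0, name: str = "SF", space: str = "lnc"
) -> KernelMatrix:
    """Radial basis function kernel K(a,b) = exp(-gamma ||x_a - x_b||^2)."""
    if gamma <= 0:
        raise ValueError("RBF bandwidth must be positive")
    X = np.array([f.vector for f in features], dtype=float)
    if X.ndim != 2:
        raise ValueError("feature vectors must share one length")
    K = np.exp(-gamma * _squared_distances(X))
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, tuple(f.id for f in features), name, space)


def expression_kernel(
    profiles: list[ExpressionProfile], gamma: float = 1.0
) -> KernelMatrix:
    """RBF kernel over L2-normalised expression profiles (bandwidth 1 default)."""
    dims = {len(p.vector) for p in profiles}
    if len(dims) != 1:
        raise ValueError(f"expression profiles have mixed dimensions {sorted(dims)}")
    feats = [
        FeatureVector(p.id, tuple(_l2_normalize(np.asarray(p.vector, dtype=float))))
        for p in profiles
    ]
    return rbf_kernel(feats, gamma=gamma, name="EXP", space="lnc")


def go_kernel(annotations: list[GOAnnotation]) -> KernelMatrix:
    """Jaccard kernel over GO term sets: K(j,s) = |t_j ∩ t_s| / |t_j ∪ t_s|.

    A protein with an empty term set gets a neutral row: 0 off-diagonal, 1 on
    the diagonal, so downstream fusion can proceed without per-row weighting.
    """
    p = len(annotations)
    K = np.zeros((p, p))
    for j in range(p):
        tj = annotations[j].terms
        K[j, j] = 1.0
        for s in range(j + 1, p):
            ts = annotations[s].terms
            if tj and ts:
                union = len(tj | ts)
                K[j, s] = K[s, j] = len(tj & ts) / union
    return KernelMatrix(K, tuple(a.id for a in annotations), "GO", "pro")


def annotation_vectors_share_terms(a, b) -> bool:
    """Positional common-terms relation between two annotation vectors: the
    sequences share terms only when they are identical position by position.
    This is the sparse rule under which <3,2,5> relates to <3,2,5> but not to
    <3,1,5>."""
    a, b = list(a), list(b)
    return len(a) == len(b) and all(x == y for x, y in zip(a, b))


def cosine_normalize(K: KernelMatrix) -> KernelMatrix:
    """K'(a,b) = K(a,b) / sqrt(K(a,a) K(b,b)); zero-diagonal rows are left as
    zeros with the diagonal set to 1."""
    V = K.values
    d = np.diag(V).copy()
    scale = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    out = V * np.outer(scale, scale)
    np.fill_diagonal(out, 1.0)
    return KernelMatrix(out, K.axis_ids, K.name, K.space)


def psd_repair(K: KernelMatrix, floor: float = 0.0) -> KernelMatrix:
    """Clip eigenvalues below ``floor`` and reconstruct; a PSD input passes
    through unchanged (to 1e-10)."""
    V = K.values
    if np.abs(V - V.T).max(initial=0.0) > 1e-8:
        raise ValueError("psd_repair requires a symmetric matrix")
    w, U = np.linalg.eigh(V)
    if w.min(initial=0.0) >= floor:
        return KernelMatrix(V, K.axis_ids, K.name, K.space)
    w = np.maximum(w, floor)
    out = (U * w) @ U.T
    out = 0.5 * (out + out.T)
    return KernelMatrix(out, K.axis_ids, K.name, K.space)


def embed_in_registry(
    K: KernelMatrix, full_ids: tuple[str, ...]
) -> KernelMatrix:
    """Embed a kernel computed over a subset of molecules into the full axis.

    Molecules missing from ``K`` get neutral rows (0 off-diagonal, 1 on the
    diagonal), the same convention as an empty GO set.
    """
    pos = {x: i for i, x in enumerate(K.axis_ids)}
    p = len(full_ids)
    out = np.eye(p)
    idx = [(i, pos[x]) for i, x in enumerate(full_ids) if x in pos]
    if idx:
        rows_full, rows_sub = map(np.array, zip(*idx))
        out[np.ix_(rows_full, rows_full)] = K.values[np.ix_(rows_sub, rows_sub)]
    np.fill_diagonal(out, 1.0)
    return KernelMatrix(out, tuple(full_ids), K.name, K.space)
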