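"""Assembly of the full kernel banks from a loaded dataset.

This is the glue between the raw inputs and the learning modules: it computes
the four kernels per space, applies PSD repair and cosine normalisation, and
embeds kernels computed on a modality subset back onto the full registry axis
with neutral rows for the missing molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .data_io import (
    ExpressionProfile,
    GOAnnotation,
    InteractionMatrix,
    MoleculeRegistry,
    PSSMProfile,
    SequenceRecord,
)
from .fastkl import DEFAULT_LAMBDA, KernelBank
from .kernels import (
    AlignmentScoring,
    GIPParams,
    KernelMatrix,
    cosine_normalize,
    ct_features,
    embed_in_registry,
    expression_kernel,
    gip_kernel,
    go_kernel,
    psd_repair,
    psepssm_features,
    rbf_kernel,
    sw_kernel,
)

LNC_KERNEL_NAMES = ("GIP", "SW", "SF", "EXP")
PRO_KERNEL_NAMES = ("GIP", "SW", "SF", "GO")


@dataclass
class PipelineConfig:
    """Every tunable knob of the prediction pipeline in one place."""

    gip: GIPParams = field(default_factory=GIPParams)
    rna_scoring: AlignmentScoring = field(
        default_factory=lambda: AlignmentScoring("rna")
    )
    pro_scoring: AlignmentScoring = field(
        default_factory=lambda: AlignmentScoring("protein")
    )
    gamma_sf: float = 1.0
    gamma_exp: float = 1.0
    pse_lag: int = 1
    fastkl_lambda: float = DEFAULT_LAMBDA
    project_simplex: bool = True
    lambda_l: float = 1.0
    lambda_p: float = 1.0


@dataclass
class LPIDataset:
    """All loaded inputs for one prediction problem."""

    interactions: InteractionMatrix
    lnc_seqs: list[SequenceRecord]
    pro_seqs: list[SequenceRecord]
    expression: list[ExpressionProfile]
    go: list[GOAnnotation]
    pssms: dict[str, PSSMProfile] = field(default_factory=dict)

    @property
    def registry(self) -> MoleculeRegistry:
        return self.interactions.registry


def _finalize(K: KernelMatrix, full_ids: tuple[str, ...], repair: bool) -> KernelMatrix:
    if repair:
        K = psd_repair(K)
    K = cosine_normalize(K)
    if K.axis_ids != full_ids:
        K = embed_in_registry(K, full_ids)
    return K


def build_static_kernels(
    dataset: LPIDataset, config: PipelineConfig | None = None
) -> tuple[dict[str, KernelMatrix], dict[str, KernelMatrix]]:
    """Kernels that do not depend on the training mask (everything but GIP).

    Returns (lnc_kernels, pro_kernels) keyed by kernel name, each aligned to
    the full registry axis.
    """
    config = config or PipelineConfig()
    reg = dataset.registry

    lnc: dict[str, KernelMatrix] = {}
    pro: dict[str, KernelMatrix] = {}

    if dataset.lnc_seqs:
        lnc["SW"] = _finalize(
            sw_kernel(dataset.lnc_seqs, config.rna_scoring, "lnc"), reg.lnc_ids, True
        )
        lnc["SF"] = _finalize(
            rbf_kernel(ct_features(dataset.lnc_seqs), config.gamma_sf, "SF", "lnc"),
            reg.lnc_ids,
            False,
        )
    if dataset.expression:
        lnc["EXP"] = _finalize(
            expression_kernel(dataset.expression, config.gamma_exp), reg.lnc_ids, False
        )

    if dataset.pro_seqs:
        pro["SW"] = _finalize(
            sw_kernel(dataset.pro_seqs, config.pro_scoring, "pro"), reg.pro_ids, True
        )
        pro["SF"] = _finalize(
            rbf_kernel(
                psepssm_features(dataset.pro_seqs, dataset.pssms, config.pse_lag),
                config.gamma_sf,
                "SF",
                "pro",
            ),
            reg.pro_ids,
            False,
        )
    annotated = {a.id: a for a in dataset.go}
    full_go = [
        annotated.get(pid, GOAnnotation(pid, frozenset())) for pid in reg.pro_ids
    ]
    pro["GO"] = _finalize(go_kernel(full_go), reg.pro_ids, True)

    return lnc, pro


def build_banks(
    F_train: InteractionMatrix,
    static_lnc: dict[str, KernelMatrix],
    static_pro: dict[str, KernelMatrix],
    config: PipelineConfig | None = None,
) -> tuple[KernelBank, KernelBank]:
    """Per-training-view kernel banks: GIP recomputed from the masked matrix,
    static kernels appended in the canonical order."""
    config = config or PipelineConfig()
    gip_l = gip_kernel(F_train, "lnc", config.gip)
    gip_p = gip_kernel(F_train, "pro", config.gip)
    lnc_members = [gip_l] + [static_lnc[k] for k in LNC_KERNEL_NAMES[1:] if k in static_lnc]
    pro_members = [gip_p] + [static_pro[k] for k in PRO_KERNEL_NAMES[1:] if k in static_pro]
    return KernelBank(lnc_members), KernelBank(pro_members)
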