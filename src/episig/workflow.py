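"""End-to-end orchestration: QC -> deconvolution -> clock -> signature -> SVM.

Thin glue over the stage modules, used by the command-line interface
and by evaluation scripts. Each step can equally be called on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import cell_deconv, classify, epi_clock, probe_qc, signature
from .cell_deconv import CellReference
from .core_io import BetaMatrix, ProbeManifest, SampleSheet, align
from .epi_clock import ClockModel


@dataclass
class DiscoveryRun:
    """Everything produced by one discovery pass."""

    filtered_beta: BetaMatrix
    qc_report: probe_qc.FilterReport
    cell_props: pd.DataFrame
    clock_result: epi_clock.ClockResult
    diff: signature.DiffMethResult
    signature_probes: list[str]
    pruned: classify.PrunedFeatureSet
    model: classify.ClassifierModel
    design: pd.DataFrame = field(repr=False, default=None)


def run_discovery(
    beta: BetaMatrix,
    sheet: SampleSheet,
    manifest: ProbeManifest,
    cell_reference: CellReference,
    clock: ClockModel,
    detp: pd.DataFrame | None = None,
    qc_params: probe_qc.QCParams | None = None,
    excluded_cell_type: str = "Neu",
    q_max: float = 0.05,
    min_abs_delta: float = 0.10,
    prune_cutoff: float = 0.90,
    svm_kernel: str = "linear",
    svm_cost: float = 1.0,
    seed: int = 0,
) -> DiscoveryRun:
    """Run the full discovery pipeline on one cohort.

    Probe QC and the clock run on all samples; the differential model,
    pruning and SVM training use discovery samples only.
    """
    beta = align(beta, sheet)
    filtered, report = probe_qc.filter_probes(beta, manifest, detp=detp, params=qc_params)

    props = cell_deconv.estimate_cell_proportions(filtered, cell_reference)
    clock_result = epi_clock.run_clock(filtered, sheet, clock)

    disc_sheet = sheet.discovery()
    disc_ids = list(disc_sheet.sample_ids)
    disc_beta = filtered.subset_samples(disc_ids)
    cov = cell_deconv.covariate_block(props.loc[disc_ids], excluded_cell_type)
    design = signature.build_design(
        disc_sheet,
        cell_props=cov,
        residuals=clock_result.table["residual"].loc[disc_ids],
    )
    diff = signature.run_differential(disc_beta, disc_sheet, design)
    sig = signature.select_signature(diff, q_max=q_max, min_abs_delta=min_abs_delta)

    pruned = classify.prune_correlated(disc_beta.subset_probes(sig), cutoff=prune_cutoff)
    model = classify.train_classifier(
        filtered, sheet, pruned, kernel=svm_kernel, cost=svm_cost, seed=seed
    )
    return DiscoveryRun(
        filtered_beta=filtered,
        qc_report=report,
        cell_props=props,
        clock_result=clock_result,
        diff=diff,
        signature_probes=sig,
        pruned=pruned,
        model=model,
        design=design,
    )
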