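"""End-to-end substantial-equivalence workflow.

Chains the stages: per-platform preprocessing (missingness filter, log,
autoscaling) -> cross-platform fusion -> design-response screen -> panel-
calibrated proof-of-safety testing -> focused OPLS-DA characterization of
each transgenic line against the control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fusion import ConsensusTable, cross_platform_correlation, fuse
from .io import AnnotationMap, PeakTable, StudyDesign, preprocess
from .oplsda import correlation_loadings, fit_oplsda
from .safety import run_safety, safety_summary
from .screen import ScreenResult, design_response_filter


@dataclass
class PipelineResult:
    preprocessed: dict
    fused: ConsensusTable
    cross_platform_r: float
    screen: ScreenResult
    safety: pd.DataFrame
    safety_summary: pd.DataFrame
    inconclusive: pd.DataFrame
    oplsda_loadings: dict = field(default_factory=dict)  # line -> DataFrame


def run_pipeline(
    tables: dict[str, PeakTable],
    design: StudyDesign,
    maps: dict[str, AnnotationMap],
    r_min: float = 0.5,
    max_missing_fraction: float = 0.30,
    screen_alpha: float = 0.05,
    safety_alpha: float = 0.05,
    ci_level: float = 0.90,
    margin_mode: str = "symmetric",
    n_orthogonal: int = 1,
    hypothetical_panel: bool = False,
) -> PipelineResult:
    """Run the full workflow and return all stage outputs.

    Safety is assessed only for peaks that pass the design-response screen
    (peaks whose variance the experimental design cannot predict have
    unclear analytical precision).  The focused OPLS-DA fits one predictive
    and ``n_orthogonal`` orthogonal components per transgenic line versus
    the control and reports correlation loadings.
    """
    pre = {pl: preprocess(t, max_missing_fraction) for pl, t in tables.items()}
    fused = fuse(pre, maps, r_min=r_min)
    _, grand_r = cross_platform_correlation(pre, maps)

    screen = design_response_filter(fused.table, design, alpha=screen_alpha)
    retained = PeakTable(fused.table.data[screen.retained_peaks],
                         platform="fused", transformed=True)

    safety = run_safety(retained, design, alpha=safety_alpha, ci_level=ci_level,
                        mode=margin_mode, hypothetical_panel=hypothetical_panel)
    summary, incon = safety_summary(safety)

    loadings: dict[str, pd.DataFrame] = {}
    control = design.control
    for line in design.transgenic_lines:
        ids = design.samples_of(control) + design.samples_of(line)
        x = fused.table.data.loc[ids].to_numpy(dtype=float)
        labels = design.table.loc[ids, "genotype"].to_numpy()
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_oplsda(x, labels, n_predictive=1, n_orthogonal=n_orthogonal)
            loadings[line] = correlation_loadings(model, x,
                                                  peak_ids=fused.table.peak_ids)
    return PipelineResult(preprocessed=pre, fused=fused, cross_platform_r=grand_r,
                          screen=screen, safety=safety, safety_summary=summary,
                          inconclusive=incon, oplsda_loadings=loadings)
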