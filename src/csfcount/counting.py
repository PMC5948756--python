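"""WBC/RBC enumeration arithmetic.

WBCs are identified in the fluorescence channel; RBCs are the bright-field
total minus the WBC count (clamped at zero with a warning, since a
fluorescence excess signals a QC problem).  Concentrations divide the
summed per-area counts by the chamber's analysis volume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import ChamberSpec
from .errors import ValidationError
from .hough import Detection, match_detections

logger = logging.getLogger(__name__)

COUNT_MODES = ("subtraction", "matched")


@dataclass(frozen=True)
class AreaCount:
    """Counts for one imaged area."""

    n_total: int
    n_wbc: int
    n_rbc: int
    clamped: bool = False


@dataclass(frozen=True)
class CountResult:
    """Aggregate counts and concentrations for one chamber run.

    Concentrations are in cells/μL; CVs are across-area dispersion within
    this run (NaN when the mean count is zero).
    """

    per_area: tuple[AreaCount, ...]
    c_wbc: float
    c_rbc: float
    c_total: float
    cv_wbc: float
    cv_rbc: float
    cv_total: float
    analysis_volume: float
    clamping_warnings: int = 0


def count_area(
    bf: Sequence[Detection],
    fl: Sequence[Detection],
    mode: str = "subtraction",
    tol: float = 3.0,
) -> AreaCount:
    """Combine paired-modality detections from one area into class counts.

    ``subtraction`` (the default): total = |bf|, WBC = |fl|,
    RBC = max(total - WBC, 0).  ``matched``: WBCs are bright-field
    detections matched to a fluorescence detection within ``tol`` μm;
    unmatched fluorescence detections still count as WBCs (and join the
    total), unmatched bright-field detections count as RBCs.
    """
    if mode not in COUNT_MODES:
        raise ValidationError("mode", f"must be one of {COUNT_MODES}")
    if mode == "subtraction":
        n_total, n_wbc = len(bf), len(fl)
        raw_rbc = n_total - n_wbc
        clamped = raw_rbc < 0
        if clamped:
            logger.warning(
                "fluorescence count (%d) exceeds bright-field count (%d); RBC clamped to 0",
                n_wbc, n_total,
            )
        return AreaCount(n_total=n_total, n_wbc=n_wbc, n_rbc=max(raw_rbc, 0), clamped=clamped)
    m = match_detections(bf, fl, tol)
    extra_wbc = len(m.unmatched_b)
    n_wbc = m.n_matched + extra_wbc
    n_rbc = len(m.unmatched_a)
    return AreaCount(n_total=len(bf) + extra_wbc, n_wbc=n_wbc, n_rbc=n_rbc, clamped=False)


def _cv(counts: np.ndarray) -> float:
    mean = counts.mean()
    if mean <= 0:
        return math.nan
    return float(counts.std(ddof=1) / mean) if counts.size > 1 else math.nan


def concentrations(per_area: Sequence[AreaCount], chamber: ChamberSpec | None = None) -> CountResult:
    """Concentrations (cells/μL) from per-area counts over the analysis volume.

    The denominator is ``chamber.analysis_volume`` in nL (588 nL by
    default, the instrument's printed constant); 1 μL = 1000 nL.
    """
    chamber = chamber or ChamberSpec()
    if chamber.analysis_volume <= 0:
        raise ValidationError("analysis_volume", "must be > 0")
    if not per_area:
        raise ValidationError("per_area", "needs at least one area")
    if len(per_area) < chamber.n_areas:
        logger.warning(
            "only %d of %d areas supplied; concentrations use the full analysis volume",
            len(per_area), chamber.n_areas,
        )
    vol_ul = chamber.analysis_volume / 1000.0
    totals = np.array([a.n_total for a in per_area], dtype=float)
    wbcs = np.array([a.n_wbc for a in per_area], dtype=float)
    rbcs = np.array([a.n_rbc for a in per_area], dtype=float)
    return CountResult(
        per_area=tuple(per_area),
        c_wbc=float(wbcs.sum() / vol_ul),
        c_rbc=float(rbcs.sum() / vol_ul),
        c_total=float(totals.sum() / vol_ul),
        cv_wbc=_cv(wbcs),
        cv_rbc=_cv(rbcs),
        cv_total=_cv(totals),
        analysis_volume=chamber.analysis_volume,
        clamping_warnings=sum(1 for a in per_area if a.clamped),
    )


def poisson_cv(expected_total_count: float) -> float:
    """Counting-statistics lower bound on the CV: 1/sqrt(N).

    With N cells expected in the analyzed volume, no counting method can
    have a replicate CV below this floor.
    """
    if expected_total_count <= 0:
        raise ValidationError("expected_total_count", "must be > 0")
    return 1.0 / math.sqrt(expected_total_count)
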