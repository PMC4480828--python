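"""2×2 contingency statistics for within/outside-region enrichment.

For a disease set and a control set counted within and outside a regulatory
track, the table cells are

=============  ==============  ===============
               within region   outside region
disease        DMW             DMO
control        DCW             DCO
=============  ==============  ===============

and the enrichment is the odds ratio ``OR = (DMW/DMO) / (DCW/DCO)`` with the
log-OR standard error ``SE = sqrt(1/DMW + 1/DMO + 1/DCW + 1/DCO)``.
Significance uses the Pearson chi-squared test on the table (1 df, no
continuity correction).

Zero cells make OR/log-OR non-finite; the default policy is to return the
non-finite value untouched (callers inspect ``math.isfinite``).  An optional
Haldane–Anscombe ``+0.5`` correction exists for plotting but is never applied
by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import RegulatoryTrack
from .variants import VariantSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Disease/control × within/outside counts (DMW, DMO, DCW, DCO)."""

    dmw: int
    dmo: int
    dcw: int
    dco: int

    def __post_init__(self) -> None:
        if min(self.dmw, self.dmo, self.dcw, self.dco) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.dmw + self.dmo + self.dcw + self.dco

    def cells(self, haldane: bool = False) -> tuple[float, float, float, float]:
        shift = 0.5 if haldane else 0.0
        return (
            self.dmw + shift,
            self.dmo + shift,
            self.dcw + shift,
            self.dco + shift,
        )


@dataclass
class EnrichmentResult:
    table: ContingencyTable2x2
    odds_ratio: float
    log_or: float
    se: float
    chi2: float
    p: float
    track_label: str = ""
    category_label: str = ""

    @property
    def finite(self) -> bool:
        return math.isfinite(self.odds_ratio) and math.isfinite(self.log_or)


def build_table(
    disease: VariantSet, control: VariantSet, track: RegulatoryTrack
) -> ContingencyTable2x2:
    """Count disease and control variants within/outside a merged track.

    Disease and control must be key-disjoint (the control is normally the
    background minus all disease sets).
    """
    shared = disease.keys() & control.keys()
    if shared:
        raise ValueError(
            f"disease and control sets share {len(shared)} variant key(s); "
            "subtract disease variants from the background first"
        )
    from .density import count_variants_in_track

    dmw = count_variants_in_track(disease, track)
    dcw = count_variants_in_track(control, track)
    return ContingencyTable2x2(dmw, len(disease) - dmw, dcw, len(control) - dcw)


def odds_ratio(t: ContingencyTable2x2, haldane: bool = False) -> float:
    """(DMW/DMO)/(DCW/DCO); zero cells yield inf/0/nan unless ``haldane``."""
    a, b, c, d = t.cells(haldane)
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(np.float64(a) * d / (np.float64(b) * c))


def log_or_and_se(
    t: ContingencyTable2x2, haldane: bool = False
) -> tuple[float, float]:
    """Natural-log odds ratio and its standard error.

    With any zero cell (and no correction) both values are returned as NaN —
    a flagged undefined result, never silently corrected.
    """
    a, b, c, d = t.cells(haldane)
    if min(a, b, c, d) <= 0:
        return (math.nan, math.nan)
    return (
        math.log((a / b) / (c / d)),
        math.sqrt(1 / a + 1 / b + 1 / c + 1 / d),
    )


def pearson_chi2(t: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-squared statistic and upper-tail p (1 df, no Yates).

    A zero row/column margin makes the test degenerate: returns (0.0, 1.0)
    with a logged warning.
    """
    a, b, c, d = t.dmw, t.dmo, t.dcw, t.dco
    n = t.n
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if n == 0 or 0 in (r1, r2, c1, c2):
        logger.warning("degenerate 2x2 table (zero margin): %s", t)
        return (0.0, 1.0)
    expected = np.array(
        [r1 * c1, r1 * c2, r2 * c1, r2 * c2], dtype=float
    ) / n
    observed = np.array([a, b, c, d], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return (stat, float(stats.chi2.sf(stat, df=1)))


def enrichment_result(
    disease: VariantSet,
    control: VariantSet,
    track: RegulatoryTrack,
    haldane: bool = False,
) -> EnrichmentResult:
    """Full enrichment of one (disease category, track) pair vs a control set."""
    t = build_table(disease, control, track)
    or_ = odds_ratio(t, haldane)
    log_or, se = log_or_and_se(t, haldane)
    chi2, p = pearson_chi2(t)
    return EnrichmentResult(
        table=t,
        odds_ratio=or_,
        log_or=log_or,
        se=se,
        chi2=chi2,
        p=p,
        track_label=track.label,
        category_label=disease.label,
    )


def chi2_batch(
    dmw: np.ndarray, dmo: np.ndarray, dcw: np.ndarray, dco: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Pearson chi-squared over many 2×2 tables.

    Uses the closed form ``N (ad - bc)^2 / (r1 r2 c1 c2)``, algebraically
    identical to the sum-over-cells statistic of :func:`pearson_chi2`;
    degenerate tables (zero margin) get statistic 0 and p 1.
    """
    a = np.asarray(dmw, dtype=float)
    b = np.asarray(dmo, dtype=float)
    c = np.asarray(dcw, dtype=float)
    d = np.asarray(dco, dtype=float)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    return stat, stats.chi2.sf(stat, df=1)
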