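"""Plasmid copy number per cell from ddPCR ratios and chromosome ploidy.

Droplet digital PCR partitions a reaction into ~20k droplets; with
template molecules Poisson-distributed across droplets, the concentration
per droplet is recovered from the fraction of positive droplets as
lambda = -ln(1 - p).  The plasmid-per-chromosome ratio is the ratio of
the target and reference channel lambdas.  Chromosome copies per cell
(ploidy) come from flow cytometry calibrated against a one-copy-per-cell
standard.  The per-cell plasmid copy range is the product of the ratio
and the ploidy bounds, truncated to integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from arseq.assays import DropletAssay, FluorescenceHistogram


class SaturatedAssayError(RuntimeError):
    """All droplets positive: lambda is unbounded, the assay is unusable."""


class UndefinedRatioError(RuntimeError):
    """Reference channel concentration is zero."""


class DegenerateSampleError(RuntimeError):
    """Sample fluorescence falls below half the one-copy unit signal."""


@dataclass(frozen=True)
class DdpcrResult:
    lambda_target: float
    lambda_reference: float
    ratio: float
    ratio_se: float
    n_droplets: int


@dataclass(frozen=True)
class PloidyEstimate:
    copies_min: int
    copies_max: int
    method: str = "fcm"  # or "asserted"

    def __post_init__(self) -> None:
        if not (1 <= self.copies_min <= self.copies_max):
            raise ValueError("need 1 <= copies_min <= copies_max")


@dataclass(frozen=True)
class CopyNumberReport:
    label: str
    ratio: float
    ploidy: PloidyEstimate
    per_cell_min: int
    per_cell_max: int


def estimate_lambda(n_positive: int, n_droplets: int) -> tuple[float, float]:
    """Poisson partition estimate of copies per droplet, with its SE.

    lambda_hat = -ln(1 - p_hat) where p_hat is the positive fraction;
    the delta-method standard error is sqrt(p_hat / ((1 - p_hat) n)).
    """
    if not (0 <= n_positive <= n_droplets) or n_droplets < 1:
        raise ValueError("need 0 <= n_positive <= n_droplets, n_droplets >= 1")
    if n_positive == n_droplets:
        raise SaturatedAssayError("all droplets positive; dilute and re-run")
    p = n_positive / n_droplets
    lam = -math.log1p(-p)
    se = math.sqrt(p / ((1.0 - p) * n_droplets))
    return lam, se


def ratio_with_ci(target: tuple[int, int], reference: tuple[int, int]) -> DdpcrResult:
    """Target/reference concentration ratio with delta-method SE.

    ``target`` and ``reference`` are (n_positive, n_droplets) for the two
    channels, treated as independent.  SE of the ratio combines the two
    lambda SEs: ratio * sqrt((se_t/l_t)^2 + (se_r/l_r)^2).
    """
    lam_t, se_t = estimate_lambda(*target)
    lam_r, se_r = estimate_lambda(*reference)
    if lam_r == 0:
        raise UndefinedRatioError("reference channel has zero concentration")
    ratio = lam_t / lam_r
    if lam_t == 0:
        ratio_se = se_t / lam_r
    else:
        ratio_se = ratio * math.sqrt((se_t / lam_t) ** 2 + (se_r / lam_r) ** 2)
    return DdpcrResult(
        lambda_target=lam_t,
        lambda_reference=lam_r,
        ratio=ratio,
        ratio_se=ratio_se,
        n_droplets=max(target[1], reference[1]),
    )


def ratio_from_assay(assay: DropletAssay) -> DdpcrResult:
    return ratio_with_ci(
        (assay.n_positive_target, assay.n_droplets),
        (assay.n_positive_reference, assay.n_droplets),
    )


def ploidy_from_histogram(
    sample: FluorescenceHistogram,
    standard: FluorescenceHistogram,
    quantiles: tuple[float, float] = (0.05, 0.95),
) -> PloidyEstimate:
    """Chromosome copies per cell, calibrated against the 1-copy standard.

    The standard's histogram mode defines the fluorescence of one
    chromosome copy; the sample's low/high quantiles divided by that unit
    give the copy-number range, rounded to the nearest integers and
    clamped to >= 1.
    """
    unit = standard.mode()
    lo = sample.quantile(quantiles[0])
    hi = sample.quantile(quantiles[1])
    if lo < 0.5 * unit:
        raise DegenerateSampleError(
            "sample fluorescence below half the one-copy unit signal"
        )
    cmin = max(1, round(lo / unit))
    cmax = max(1, round(hi / unit))
    return PloidyEstimate(copies_min=cmin, copies_max=max(cmin, cmax), method="fcm")


def per_cell_copy_range(ratio: float, ploidy: PloidyEstimate) -> tuple[int, int]:
    """Per-cell plasmid copy bounds: floor(ratio x ploidy bound).

    Truncation (not rounding) is the rule: a cell cannot hold a fraction
    of a plasmid, so the bound is the whole number of copies implied by
    the ratio at each ploidy extreme.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    return (
        math.floor(ratio * ploidy.copies_min),
        math.floor(ratio * ploidy.copies_max),
    )


def copy_number_report(label: str, ratio: float, ploidy: PloidyEstimate) -> CopyNumberReport:
    lo, hi = per_cell_copy_range(ratio, ploidy)
    return CopyNumberReport(label=label, ratio=ratio, ploidy=ploidy,
                            per_cell_min=lo, per_cell_max=hi)
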