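"""Simulators for droplet digital PCR and flow-cytometry readouts.

The droplet model follows ddPCR partition statistics: template molecules
distribute into droplets as Poisson(lambda) per channel, so a droplet is
positive with probability 1 - exp(-lambda), independently per channel.
The flow-cytometry model gives each cell a fluorescence proportional to
its chromosome copy number with multiplicative lognormal noise, binned
into a histogram, next to a one-copy-per-cell standard used to calibrate
the unit signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DropletAssay:
    """Observed positive-droplet counts with the simulation truth retained."""

    n_droplets: int
    n_positive_target: int
    n_positive_reference: int
    true_lambda_target: float
    true_lambda_reference: float

    def __post_init__(self) -> None:
        for n in (self.n_positive_target, self.n_positive_reference):
            if not (0 <= n <= self.n_droplets):
                raise ValueError("positive count outside [0, n_droplets]")


@dataclass(frozen=True)
class FluorescenceHistogram:
    """Binned per-cell fluorescence (arbitrary units)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    label: str  # "standard" or "sample"

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts/bin_edges length mismatch")
        if self.counts.sum() <= 0:
            raise ValueError("empty histogram")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mode(self) -> float:
        return float(self.centers[int(np.argmax(self.counts))])

    def quantile(self, q: float) -> float:
        cum = np.cumsum(self.counts)
        k = int(np.searchsorted(cum, q * cum[-1]))
        return float(self.centers[min(k, len(self.centers) - 1)])


def simulate_droplets(
    true_lambda_target: float,
    true_lambda_reference: float,
    n_droplets: int,
    seed: int = 0,
) -> DropletAssay:
    """Simulate a two-channel droplet assay.

    Each of ``n_droplets`` droplets is positive for a channel with
    probability 1 - exp(-lambda), independently between channels.
    """
    if true_lambda_target < 0 or true_lambda_reference < 0:
        raise ValueError("lambda must be >= 0")
    if n_droplets < 1:
        raise ValueError("need at least one droplet")
    rng = np.random.default_rng(seed)
    p_t = -np.expm1(-true_lambda_target)
    p_r = -np.expm1(-true_lambda_reference)
    return DropletAssay(
        n_droplets=n_droplets,
        n_positive_target=int(rng.binomial(n_droplets, p_t)),
        n_positive_reference=int(rng.binomial(n_droplets, p_r)),
        true_lambda_target=true_lambda_target,
        true_lambda_reference=true_lambda_reference,
    )


# fluorescence of one chromosome copy, arbitrary units; fixed calibration scale
UNIT_SIGNAL = 100.0
_N_BINS = 256


def simulate_fcm(
    copies_per_cell_distribution: dict[int, float],
    n_cells: int,
    cv: float = 0.1,
    standard: bool = False,
    seed: int = 0,
) -> FluorescenceHistogram:
    """Simulate a stained-DNA fluorescence histogram.

    Each cell draws a chromosome copy number from the given discrete
    distribution (forced to 1 for the calibration standard) and emits
    fluorescence copies * UNIT_SIGNAL * lognormal noise with coefficient
    of variation ``cv``.  Binned on a fixed grid so sample and standard
    histograms are directly comparable.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if cv <= 0:
        raise ValueError("cv must be positive")
    items = sorted(copies_per_cell_distribution.items())
    if any(k < 1 for k, _ in items):
        raise ValueError("copy numbers must be positive integers")
    rng = np.random.default_rng(seed)
    if standard:
        copies = np.ones(n_cells)
    else:
        vals = np.array([k for k, _ in items], dtype=float)
        probs = np.array([v for _, v in items], dtype=float)
        probs = probs / probs.sum()
        copies = rng.choice(vals, size=n_cells, p=probs)
    # lognormal with E[noise]=1 and CV=cv
    sigma2 = np.log1p(cv**2)
    noise = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n_cells)
    signal = copies * UNIT_SIGNAL * noise
    max_copy = 1 if standard else max(k for k, _ in items)
    hi = UNIT_SIGNAL * (max_copy + 4)
    edges = np.linspace(0.0, hi, _N_BINS + 1)
    counts, _ = np.histogram(signal, bins=edges)
    return FluorescenceHistogram(
        bin_edges=edges,
        counts=counts,
        label="standard" if standard else "sample",
    )
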