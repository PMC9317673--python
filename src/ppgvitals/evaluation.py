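"""Agreement statistics: Bland-Altman analysis and mean percentage error.

Device-derived vitals are compared against a reference stream after
timestamp-based pairing.  Bland-Altman plots paired differences against
paired means with bias and +-1.96 SD limits of agreement; the mean
percentage error summarises accuracy as mean(100 |derived - ref| / ref).
The difference convention throughout is derived minus reference, and the
limits of agreement use the sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass
class PairedSeries:
    """Time-aligned derived/reference value pairs."""

    t: np.ndarray
    derived: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.derived = np.asarray(self.derived, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if not (len(self.t) == len(self.derived) == len(self.reference)):
            raise ValidationError("paired series must have equal lengths")
        for a in (self.t, self.derived, self.reference):
            if np.any(~np.isfinite(a)):
                raise ValidationError("paired series must be finite")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    means: np.ndarray       # per-pair (derived + reference) / 2, the x axis
    differences: np.ndarray # per-pair derived - reference, the y axis


def bland_altman(pairs: PairedSeries) -> BlandAltmanResult:
    """Bias and +-1.96 SD limits of agreement of derived vs reference."""
    if len(pairs) < 2:
        raise ValidationError("Bland-Altman needs at least 2 pairs")
    diffs = pairs.derived - pairs.reference
    means = (pairs.derived + pairs.reference) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=means,
        differences=diffs,
    )


def mean_percentage_error(pairs: PairedSeries) -> float:
    """Mean of 100 |derived - reference| / reference over all pairs."""
    if len(pairs) < 1:
        raise ValidationError("need at least one pair")
    if np.any(pairs.reference == 0):
        raise ValidationError("reference values must be nonzero")
    return float(
        np.mean(100.0 * np.abs(pairs.derived - pairs.reference) / np.abs(pairs.reference))
    )


def pair_by_timestamp(
    t_derived: np.ndarray,
    x_derived: np.ndarray,
    t_reference: np.ndarray,
    x_reference: np.ndarray,
    tolerance: float,
) -> tuple[PairedSeries, int]:
    """Nearest-neighbour one-to-one matching of two timestamped streams.

    Each derived sample is matched to the closest unused reference sample
    within ``tolerance`` seconds (both streams must be time-sorted).
    Returns the paired series (timestamped at the derived times) and the
    total count of unmatched entries from both streams.
    """
    t_d = np.asarray(t_derived, dtype=float)
    t_r = np.asarray(t_reference, dtype=float)
    x_d = np.asarray(x_derived, dtype=float)
    x_r = np.asarray(x_reference, dtype=float)
    if np.any(np.diff(t_d) < 0) or np.any(np.diff(t_r) < 0):
        raise ValidationError("both series must be time-sorted")

    used = np.zeros(len(t_r), dtype=bool)
    ti, di, ri = [], [], []
    for i, t in enumerate(t_d):
        j = int(np.searchsorted(t_r, t))
        best, best_dt = -1, tolerance
        for cand in (j - 1, j):
            if 0 <= cand < len(t_r) and not used[cand]:
                dt = abs(t_r[cand] - t)
                if dt <= best_dt:
                    best, best_dt = cand, dt
        if best >= 0:
            used[best] = True
            ti.append(t)
            di.append(x_d[i])
            ri.append(x_r[best])
    pairs = PairedSeries(t=np.asarray(ti), derived=np.asarray(di), reference=np.asarray(ri))
    unmatched = (len(t_d) - len(pairs)) + (len(t_r) - len(pairs))
    return pairs, unmatched


def bland_altman_plot(result: BlandAltmanResult, path, title: str = "Bland-Altman"):
    """Write the standard agreement plot (means vs differences with bias
    and limit-of-agreement lines) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.means, result.differences, s=18, alpha=0.7)
    ax.axhline(result.bias, color="k", lw=1.2, label=f"bias = {result.bias:.2f}")
    for y, name in ((result.loa_low, "-1.96 SD"), (result.loa_high, "+1.96 SD")):
        ax.axhline(y, color="r", ls="--", lw=1.0, label=f"{name} = {y:.2f}")
    ax.set_xlabel("mean of paired readings")
    ax.set_ylabel("difference (derived - reference)")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
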