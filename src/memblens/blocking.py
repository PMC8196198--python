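"""Blocking (successive pair-averaging) standard errors.

The naive standard error of the mean, s / sqrt(N), underestimates the true
error of a positively autocorrelated time series.  The blocking transform
replaces the series by the means of consecutive pairs; repeating it halves
the length each level while the standard-error estimate of the blocked series
climbs toward the true error and then plateaus once blocks are longer than
the correlation time.  The reported error is the plateau value: the first
level at which the estimate stops increasing by more than its own statistical
uncertainty, SE / sqrt(2 (n_blocks - 1)).  If no plateau is reached before
the series becomes too short, the maximum over levels is returned and the
result flagged as not converged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BlockingResult", "blocking_se", "naive_se"]

MIN_LENGTH = 8
MIN_BLOCKS = 4


@dataclass(frozen=True)
class BlockingResult:
    se: float
    plateau_level: int
    converged: bool  # False when the fallback (max over levels) was used
    block_sizes: np.ndarray  # per level
    se_curve: np.ndarray  # SE estimate per level
    se_uncertainty: np.ndarray  # estimated sigma of each SE estimate


def naive_se(series: np.ndarray) -> float:
    x = np.asarray(series, dtype=np.float64)
    if len(x) < 2:
        return 0.0
    return float(x.std(ddof=1) / np.sqrt(len(x)))


def blocking_se(series: np.ndarray) -> BlockingResult:
    """Flyvbjerg–Petersen blocking estimate of the SE of the mean."""
    x = np.asarray(series, dtype=np.float64).ravel()
    if len(x) < MIN_LENGTH:
        raise ValueError(f"blocking needs >= {MIN_LENGTH} points, got {len(x)}")
    sizes: list[int] = []
    ses: list[float] = []
    uncs: list[float] = []
    block = 1
    while len(x) >= MIN_BLOCKS:
        n = len(x)
        se = float(x.std(ddof=1) / np.sqrt(n))
        sizes.append(block)
        ses.append(se)
        uncs.append(se / np.sqrt(2.0 * (n - 1)))
        if n % 2:
            x = x[:-1]
        x = 0.5 * (x[0::2] + x[1::2])
        block *= 2
    ses_arr = np.array(ses)
    uncs_arr = np.array(uncs)
    plateau = None
    for k in range(len(ses_arr) - 1):
        if ses_arr[k + 1] <= ses_arr[k] + uncs_arr[k]:
            plateau = k
            break
    if plateau is None:
        k_max = int(np.argmax(ses_arr))
        return BlockingResult(
            se=float(ses_arr[k_max]),
            plateau_level=k_max,
            converged=False,
            block_sizes=np.array(sizes),
            se_curve=ses_arr,
            se_uncertainty=uncs_arr,
        )
    # the estimate has settled: report the larger of the two level values
    se = float(max(ses_arr[plateau], ses_arr[plateau + 1]))
    return BlockingResult(
        se=se,
        plateau_level=plateau,
        converged=True,
        block_sizes=np.array(sizes),
        se_curve=ses_arr,
        se_uncertainty=uncs_arr,
    )
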