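"""Small exactly-specified statistics used around the screen.

Percent transduction (virus titration), Bliss-independence drug synergy,
relative proliferation fold change, and validation accuracy.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def percent_transduction(n_with_puro: float, n_without_puro: float) -> float:
    """100 x cells surviving puromycin / cells without puromycin."""
    if n_without_puro <= 0:
        raise ValueError("cell number without puromycin must be > 0")
    if n_with_puro < 0:
        raise ValueError("cell numbers must be >= 0")
    return 100.0 * n_with_puro / n_without_puro


def bliss_expected(i_a: np.ndarray, i_b: np.ndarray) -> np.ndarray:
    """Bliss independence surface: iA + iB - iA*iB (outer over dose grids)."""
    i_a = np.asarray(i_a, dtype=float)
    i_b = np.asarray(i_b, dtype=float)
    return i_a[:, None] + i_b[None, :] - i_a[:, None] * i_b[None, :]


def bliss_excess(
    observed: pd.DataFrame, clip_negative_inhibition: bool = False
) -> tuple[pd.DataFrame, float]:
    """Observed minus Bliss-expected inhibition for every both-drug cell.

    ``observed`` is an inhibition-fraction matrix whose first row/column are
    the single-agent curves (dose 0 of the other drug).  Returns the excess
    over the interior cells and the mean synergy score in percentage points
    (mean excess x 100); positive means synergy.
    """
    obs = observed.to_numpy(dtype=float)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("matrix needs at least 2 doses per drug (including dose 0)")
    if clip_negative_inhibition:
        obs = np.clip(obs, 0.0, None)
    if (obs < 0).any() or (obs > 1).any():
        raise ValueError("inhibition values must lie in [0, 1]")
    i_a = obs[:, 0]
    i_b = obs[0, :]
    expected = bliss_expected(i_a, i_b)
    excess = (obs - expected)[1:, 1:]
    out = pd.DataFrame(excess, index=observed.index[1:], columns=observed.columns[1:])
    return out, float(excess.mean() * 100.0)


def relative_foldchange(line_t0, line_t14, ref_t0, ref_t14):
    """Growth of a line relative to the reference line: (T14/T0)/(refT14/refT0).

    Accepts scalars or equal-length arrays (e.g. triplicates), returning a
    scalar or element-wise array of ratios.
    """
    arrs = [np.asarray(x, dtype=float) for x in (line_t0, line_t14, ref_t0, ref_t14)]
    if any((a <= 0).any() for a in arrs):
        raise ValueError("all cell counts must be > 0")
    lt0, lt14, rt0, rt14 = arrs
    out = (lt14 / lt0) / (rt14 / rt0)
    return float(out) if out.ndim == 0 else out


def foldchange_summary(ratios: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation of replicate fold changes."""
    r = np.asarray(ratios, dtype=float)
    if r.size < 1:
        raise ValueError("no replicate values")
    sd = float(r.std(ddof=1)) if r.size > 1 else 0.0
    return float(r.mean()), sd


def validation_accuracy(n_confirmed: int, n_tested: int) -> float:
    """Percentage of screen calls confirmed individually, to one decimal."""
    if n_tested <= 0:
        raise ValueError("n_tested must be > 0")
    if not 0 <= n_confirmed <= n_tested:
        raise ValueError("n_confirmed must lie in [0, n_tested]")
    return round(100.0 * n_confirmed / n_tested, 1)
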