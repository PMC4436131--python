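"""Cosinor rhythmicity analysis, FDR screening and serum statistics.

The rhythmicity test is the classical single-harmonic cosinor: least-squares
fit of ``y = mesor + A*cos(2*pi*t/tau) + B*sin(2*pi*t/tau)`` with amplitude
``sqrt(A^2 + B^2)`` and acrophase the peak time of the fitted curve in
[0, tau). Significance is the F-test of the two harmonic terms against the
intercept-only model. Batch screens correct p-values per condition with
Benjamini-Hochberg; q < 0.05 flags a probe as rhythmically expressed.

Higher harmonics are available through ``harmonics > 1`` (the amplitude and
acrophase then describe the full fitted waveform), but all defaults report
the fundamental period only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError, InsufficientDataError

_TINY = 1e-30


@dataclass(frozen=True)
class CosinorResult:
    mesor: float
    amplitude: float
    acrophase: float
    tau: float
    f_stat: float
    p_value: float
    n: int
    q_value: float = float("nan")


def _design_matrix(times: np.ndarray, tau: float, harmonics: int) -> np.ndarray:
    cols = [np.ones_like(times)]
    for h in range(1, harmonics + 1):
        w = 2.0 * np.pi * h * times / tau
        cols.extend([np.cos(w), np.sin(w)])
    return np.column_stack(cols)


def _flat_mask(rss0, mean, n):
    """A series is flat when its total variation is numerical noise only."""
    scale = np.maximum(np.abs(np.asarray(mean, float)), 1.0)
    return np.asarray(rss0, float) <= n * (1e-10 * scale) ** 2


def _f_test(rss0, rss1, n, harmonics, flat):
    """Vector-safe F and p for harmonic terms vs intercept-only."""
    df1 = 2 * harmonics
    df2 = n - df1 - 1
    rss0 = np.asarray(rss0, float)
    rss1 = np.asarray(rss1, float)
    perfect = ~flat & (rss1 <= np.maximum(_TINY, rss0 * 1e-14))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / df1) / (rss1 / df2)
        p = stats.f.sf(f, df1, df2)
    f = np.where(flat, 0.0, np.where(perfect, np.inf, np.maximum(f, 0.0)))
    p = np.where(flat, 1.0, np.where(perfect, 0.0, p))
    return f, p


def cosinor_fit(times, values, tau: float = 24.0, harmonics: int = 1) -> CosinorResult:
    """Least-squares cosinor fit of one series at period ``tau``.

    Requires at least ``2*harmonics + 2`` observations over at least
    ``2*harmonics + 1`` distinct times. A flat series returns amplitude 0
    with F = 0 and p = 1.
    """
    if tau <= 0:
        raise ConfigError("period tau must be > 0")
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise DataError("times and values must be 1-D and equally long")
    n_params = 2 * harmonics + 1
    if len(t) < n_params + 1:
        raise InsufficientDataError(
            f"cosinor needs >= {n_params + 1} observations, got {len(t)}"
        )
    if len(np.unique(t % tau)) < n_params:
        raise InsufficientDataError(
            f"cosinor with {harmonics} harmonic(s) needs >= {n_params} distinct times"
        )
    x = _design_matrix(t, tau, harmonics)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    rss1 = float(np.sum((y - fitted) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    flat = _flat_mask(rss0, y.mean(), len(t))
    f, p = _f_test(rss0, rss1, len(t), harmonics, flat)

    mesor = float(beta[0])
    a1, b1 = float(beta[1]), float(beta[2])
    if flat:
        return CosinorResult(
            mesor=float(y.mean()), amplitude=0.0, acrophase=0.0, tau=tau,
            f_stat=0.0, p_value=1.0, n=len(t),
        )
    if harmonics == 1:
        amplitude = float(np.hypot(a1, b1))
        acrophase = 0.0 if amplitude == 0 else float(
            (np.arctan2(b1, a1) * tau / (2.0 * np.pi)) % tau
        )
    else:
        grid = np.linspace(0.0, tau, 8192, endpoint=False)
        curve = _design_matrix(grid, tau, harmonics) @ beta
        peak = int(np.argmax(curve))
        acrophase = float(grid[peak])
        amplitude = float((curve.max() - curve.min()) / 2.0)
    return CosinorResult(
        mesor=mesor,
        amplitude=amplitude,
        acrophase=acrophase,
        tau=tau,
        f_stat=float(f),
        p_value=float(p),
        n=len(t),
    )


def cosinor_fit_matrix(times, values, tau: float = 24.0) -> pd.DataFrame:
    """Vectorized single-harmonic cosinor over many series sharing one time grid.

    ``values`` is (series x observations); returns one row per series with
    mesor, amplitude, acrophase, f_stat and p_value.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if y.ndim != 2 or y.shape[1] != len(t):
        raise DataError("values must be 2-D with one column per time point")
    if len(t) < 4 or len(np.unique(t % tau)) < 3:
        raise InsufficientDataError("cosinor needs >= 4 observations over >= 3 distinct times")
    x = _design_matrix(t, tau, 1)
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)  # (3, m)
    resid = y - (x @ beta).T
    rss1 = np.einsum("ij,ij->i", resid, resid)
    means = y.mean(axis=1)
    centered = y - means[:, None]
    rss0 = np.einsum("ij,ij->i", centered, centered)
    flat = _flat_mask(rss0, means, len(t))
    f, p = _f_test(rss0, rss1, len(t), 1, flat)
    amplitude = np.where(flat, 0.0, np.hypot(beta[1], beta[2]))
    acrophase = np.where(
        amplitude == 0, 0.0, (np.arctan2(beta[2], beta[1]) * tau / (2.0 * np.pi)) % tau
    )
    index = values.index if isinstance(values, pd.DataFrame) else pd.RangeIndex(y.shape[0])
    return pd.DataFrame(
        {
            "mesor": beta[0],
            "amplitude": amplitude,
            "acrophase": acrophase,
            "f_stat": f,
            "p_value": p,
        },
        index=index,
    )


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    _, q, *_ = multipletests(p, method="fdr_bh")
    return q


def rhythmicity_screen(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    stage: str,
    protocol: str | None = None,
    tau: float = 24.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Cosinor-screen every probe within one experimental condition.

    The condition is a stage, optionally restricted to one rotation protocol.
    Returns per-probe cosinor statistics plus BH q-values (corrected within
    this screen) and the ``rhythmic`` flag q < ``fdr``.
    """
    mask = design["stage"] == stage
    if protocol is not None:
        mask &= design["protocol"] == protocol
    sub = design[mask]
    if len(sub) < 4 or sub["zt"].nunique() < 3:
        raise DataError(
            f"condition stage={stage!r} protocol={protocol!r} selects "
            f"{len(sub)} samples over {sub['zt'].nunique()} ZTs; need >= 4 over >= 3"
        )
    result = cosinor_fit_matrix(sub["zt"].to_numpy(), matrix[sub["sample_id"]], tau=tau)
    result["q_value"] = benjamini_hochberg(result["p_value"].to_numpy())
    result["rhythmic"] = result["q_value"] < fdr
    result.index.name = "probe_id"
    return result


def screen_all_stages(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    tau: float = 24.0,
    fdr: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """One rhythmicity screen per stage present in the design (protocols pooled)."""
    return {
        stage: rhythmicity_screen(matrix, design, stage, tau=tau, fdr=fdr)
        for stage in design["stage"].unique()
    }


@dataclass(frozen=True)
class GrubbsResult:
    retained: np.ndarray
    outliers: pd.DataFrame  # columns: value, g_stat
    alpha: float

    @property
    def n_flagged(self) -> int:
        return len(self.outliers)


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t distribution."""
    t2 = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def grubbs_screen(values, alpha: float = 0.1) -> GrubbsResult:
    """Iterative two-sided Grubbs outlier screen.

    Repeatedly flags the single most extreme point whose studentized
    deviation G exceeds the two-sided critical value at ``alpha``, until no
    point is flagged or only three points remain. A zero-variance sample
    flags nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise DataError("Grubbs screen needs a 1-D sample of n >= 3")
    if not 0 < alpha < 1:
        raise ConfigError("alpha must lie in (0, 1)")
    retained = x.copy()
    flagged = []
    while len(retained) > 3:
        sd = retained.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(retained - retained.mean())
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g > grubbs_critical_value(len(retained), alpha):
            flagged.append({"value": retained[i], "g_stat": g})
            retained = np.delete(retained, i)
        else:
            break
    return GrubbsResult(
        retained=retained,
        outliers=pd.DataFrame(flagged, columns=["value", "g_stat"]),
        alpha=alpha,
    )


def serum_group_compare(group_a, group_b) -> dict[str, float]:
    """Equal-variance two-sample t-test plus percent change of the means.

    Percent change is ``100 * (mean_b - mean_a) / mean_a``. Two degenerate
    zero-variance groups with equal means give p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("each group needs n >= 2")
    percent = 100.0 * (b.mean() - a.mean()) / a.mean()
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        t = 0.0 if p == 1.0 else float("inf")
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return {"t_stat": float(t), "p_value": float(p), "percent_change": float(percent)}


def circular_distance(a: float, b: float, tau: float = 24.0) -> float:
    """Minimal distance between two phases on a circle of circumference tau."""
    d = abs(a - b) % tau
    return min(d, tau - d)
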