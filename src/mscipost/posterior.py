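"""MCMC sample-table I/O and posterior summaries (mean, HPD, ESS).

Tables are tab-separated with a header row of parameter names.  The
bpp ``mcmc.txt`` dialect — a leading generation-index column, usually
``Gen`` — is accepted; that column is carried through but excluded from
summaries.

Summaries assume the table has already been relabeled; a bimodal phi
column is a symptom of unremoved label switching, and ``summarize``
emits an advisory warning when it sees one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PosteriorSummary",
    "read_samples",
    "write_samples",
    "hpd_interval",
    "ess",
    "summarize",
    "looks_bimodal",
]

GEN_COLUMNS = ("Gen", "gen", "Iteration", "iter")


@dataclass
class PosteriorSummary:
    table: pd.DataFrame  # columns: name, mean, hpd_lo, hpd_hi, ess, n

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.set_index("name").loc[name]


def read_samples(path) -> pd.DataFrame:
    """Read a TSV sample table with a header row.

    All cells must be finite numbers; ragged rows, non-numeric cells and
    empty files are errors naming the offending row and column.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty sample file") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: sample file has a header but no rows")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))
        if bad.size:
            raise ValueError(
                f"{path}: non-numeric or non-finite value at row {bad[0] + 1}, column {col!r}"
            )
        df[col] = vals
    return df


def write_samples(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def _summary_columns(table: pd.DataFrame) -> list[str]:
    cols = list(table.columns)
    if cols and cols[0] in GEN_COLUMNS:
        cols = cols[1:]
    return cols


def hpd_interval(values, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous window of ceil(level * N) order statistics;
    ties broken by the smallest lower endpoint."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("HPD needs at least two values")
    m = math.ceil(level * n)
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: lowest start
    return float(x[i]), float(x[i + m - 1])


def ess(values) -> float:
    """Effective sample size N / (1 + 2 * sum of autocorrelations), with
    the sum truncated by the initial-positive-sequence rule (stop at the
    first nonpositive pair rho_{2m} + rho_{2m+1}); clipped to [1, N].

    A constant sequence has no autocorrelation signal; it is reported as
    ESS = N with a warning.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("ESS needs at least 10 values")
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0.0:
        warnings.warn("constant sequence: ESS reported as N")
        return float(n)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n]
    rho = acov / acov[0]
    tau = -1.0  # running 2*sum(Gamma_m); Gamma_0 includes rho_0 = 1
    for m2 in range(0, n - 1, 2):
        pair = rho[m2] + (rho[m2 + 1] if m2 + 1 < n else 0.0)
        if pair <= 0.0:
            break
        tau += 2.0 * pair
    tau = max(tau, 1e-12)
    return float(np.clip(n / tau, 1.0, n))


def looks_bimodal(values) -> bool:
    """Dip heuristic for unit-interval columns: compare the mass in the
    middle decile of the data range with the flanking deciles; advisory
    only."""
    x = np.asarray(values, dtype=float)
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:
        return False
    u = (x - lo) / (hi - lo)
    mid = np.mean((u >= 0.45) & (u < 0.55))
    flanks = 0.5 * (np.mean((u >= 0.05) & (u < 0.15)) + np.mean((u >= 0.85) & (u < 0.95)))
    both_sides = np.mean(u < 0.5) > 0.2 and np.mean(u >= 0.5) > 0.2
    return bool(both_sides and flanks > 0 and mid < 0.5 * flanks)


def summarize(table: pd.DataFrame, level: float = 0.95, burnin: int = 0) -> PosteriorSummary:
    """Per-column mean, HPD interval and ESS.

    The caller is responsible for relabeling first; phi-like columns
    (all values in [0, 1]) that look bimodal trigger a warning since a
    two-tower marginal invalidates the mean and interval.
    """
    if burnin:
        table = table.iloc[burnin:]
    rows = []
    for col in _summary_columns(table):
        x = table[col].to_numpy(dtype=float)
        if np.all((x >= 0.0) & (x <= 1.0)) and looks_bimodal(x):
            warnings.warn(
                f"column {col!r} looks bimodal; was the sample relabeled before summarizing?"
            )
        if x.size >= 2 and np.ptp(x) == 0.0:
            lo, hi = float(x[0]), float(x[0])
        else:
            lo, hi = hpd_interval(x, level)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e = ess(x) if x.size >= 10 else float(x.size)
        rows.append({"name": col, "mean": float(x.mean()), "hpd_lo": lo,
                     "hpd_hi": hi, "ess": e, "n": int(x.size)})
    return PosteriorSummary(table=pd.DataFrame(rows))
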