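"""Label-switching removal for MCMC samples under BDI models.

An MCMC chain exploring a posterior with unidentifiable mirror towers
switches the meaning of the tower-specific parameters mid-run, so naive
column means and credibility intervals are corrupted (the mean of an
introgression probability tends to 1/2 regardless of the data).  The
relabeling algorithms here map every draw onto one chosen tower:

* **CoG0** — iterative center-of-gravity: recompute the mean of the
  event parameters over current positions, then move each draw to the
  transform image closest to it in Euclidean distance.
* **CoGN** — the same with per-coordinate variance weights, so phi and
  theta coordinates on very different scales contribute comparably.
* **beta-gamma** — fit independent beta densities to the phi columns
  and gamma densities to the theta columns by maximum likelihood, then
  move each draw to the image with the highest log density; alternate
  until no label changes.  The log likelihood never decreases.

The relabelers are scikit-learn style transformers operating on pandas
DataFrames whose columns include the event parameters (by default named
``phi_<node>`` / ``theta_<node>``; a ``column_map`` translates other
headers, e.g. bpp's ``mcmc.txt`` dialect).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.base import BaseEstimator, TransformerMixin

from .model import MSciModel, detect_bdi_events
from .towers import TowerMapping, double_bdi_mappings, find_stacked_pairs, identity_mapping, single_bdi_mapping

__all__ = [
    "PHI_CLAMP",
    "THETA_CLAMP",
    "BetaGammaFit",
    "RelabelResult",
    "CoGRelabeler",
    "BetaGammaRelabeler",
    "init_labels",
    "distance",
    "cog_relabel",
    "beta_gamma_relabel",
    "fit_beta_ml",
    "fit_gamma_ml",
    "beta_gamma_loglik",
    "relabel_all",
    "relabel_accuracy",
]

PHI_CLAMP = 1e-9  # phi clamped to [PHI_CLAMP, 1 - PHI_CLAMP] for density evaluation
THETA_CLAMP = 1e-12  # theta clamped to >= THETA_CLAMP for density evaluation


# ---------------------------------------------------------------------------
# shared machinery


def _mapping_params(mappings: list[TowerMapping]) -> list[str]:
    """Ordered union of parameters any mapping touches (phi first)."""
    seen: dict[str, None] = {}
    for m in mappings:
        for t, s, _ in m.moves:
            seen.setdefault(t, None)
            seen.setdefault(s, None)
    params = list(seen)
    return sorted(params, key=lambda p: (not p.startswith("phi"), params.index(p)))


def _columns_for(params: list[str], column_map: dict[str, str] | None) -> list[str]:
    cmap = column_map or {}
    return [cmap.get(p, p) for p in params]


def _check_table(X: pd.DataFrame, cols: list[str]) -> np.ndarray:
    if not isinstance(X, pd.DataFrame):
        raise TypeError("sample table must be a pandas DataFrame")
    missing = [c for c in cols if c not in X.columns]
    if missing:
        raise KeyError(f"sample table is missing column(s): {missing}")
    M = X[cols].to_numpy(dtype=float)
    if M.shape[0] < 1:
        raise ValueError("sample table must have at least one row")
    if not np.all(np.isfinite(M)):
        raise ValueError("sample table contains non-finite values in event columns")
    return M


def _images(M: np.ndarray, mappings: list[TowerMapping], params: list[str]) -> np.ndarray:
    """(T, N, k) array of the table under each transform."""
    idx = {p: j for j, p in enumerate(params)}
    out = np.empty((len(mappings), *M.shape))
    for z, mp in enumerate(mappings):
        img = M.copy()
        for target, source, comp in mp.moves:
            v = M[:, idx[source]]
            img[:, idx[target]] = 1.0 - v if comp else v
        out[z] = img
    return out


def _phi_mask(params: list[str]) -> np.ndarray:
    return np.array([p.startswith("phi") for p in params])


def _lower_upper_phis(mappings: list[TowerMapping]) -> tuple[list[str], list[str]]:
    """phi parameters of the lower (and, for double-BDI, upper) event.

    The lower event's phis are the self-complement targets of the z=2
    transform; the upper event's those of z=1.
    """
    def self_comp(m: TowerMapping) -> list[str]:
        return [t for t, s, c in m.moves if c and t == s]

    if len(mappings) == 2:
        return self_comp(mappings[1]), []
    return self_comp(mappings[2]), self_comp(mappings[1])


def init_labels(
    table: pd.DataFrame,
    mappings: list[TowerMapping],
    column_map: dict[str, str] | None = None,
) -> np.ndarray:
    """Initial transform indicator per draw.

    Two towers: z = 0 iff phi_X + phi_Y < 1, else 1 (the boundary falls
    in "otherwise").  Four towers (double-BDI): among the four images
    prefer the lowest-index transform with phi_X + phi_Y < 1 and
    phi_Z + phi_W < 1, then phi_X + phi_Y < 1 alone, else the lowest
    index minimizing phi_X + phi_Y — preferring the tower in which the
    introgression probabilities are small.
    """
    params = _mapping_params(mappings)
    cols = _columns_for(params, column_map)
    M = _check_table(table, cols)
    lower_phis, upper_phis = _lower_upper_phis(mappings)
    jl = [params.index(p) for p in lower_phis]
    if len(mappings) == 2:
        s = M[:, jl].sum(axis=1)
        return np.where(s < 1.0, 0, 1)
    ju = [params.index(p) for p in upper_phis]
    imgs = _images(M, mappings, params)
    s_low = imgs[:, :, jl].sum(axis=2)  # (T, N)
    s_up = imgs[:, :, ju].sum(axis=2)
    ok_both = (s_low < 1.0) & (s_up < 1.0)
    ok_low = s_low < 1.0
    z = np.argmin(s_low, axis=0)
    has_low = ok_low.any(axis=0)
    z[has_low] = np.argmax(ok_low[:, has_low], axis=0)
    has_both = ok_both.any(axis=0)
    z[has_both] = np.argmax(ok_both[:, has_both], axis=0)
    return z


def distance(point, center, weights=None) -> float:
    """Euclidean (CoG0) or variance-normalized (CoGN) distance."""
    p = np.asarray(point, dtype=float)
    c = np.asarray(center, dtype=float)
    if p.shape != c.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {c.shape}")
    if weights is None:
        return float(np.sqrt(np.sum((p - c) ** 2)))
    w = np.asarray(weights, dtype=float)
    if w.shape != p.shape:
        raise ValueError("weights length mismatch")
    if np.any(w <= 0):
        raise ValueError("weights must be positive variances")
    return float(np.sqrt(np.sum((p - c) ** 2 / w)))


def _keep_current_argbest(score: np.ndarray, z: np.ndarray, maximize: bool) -> np.ndarray:
    """Per-row best transform with ties resolved in favor of the current
    label (guarantees termination with the monotone objective)."""
    best = score.max(axis=0) if maximize else score.min(axis=0)
    cand = np.argmax(score, axis=0) if maximize else np.argmin(score, axis=0)
    cur = score[z, np.arange(score.shape[1])]
    return np.where(cur == best, z, cand)


# ---------------------------------------------------------------------------
# results


@dataclass
class BetaGammaFit:
    """Per-column beta/gamma ML parameters, all positive and finite."""

    beta: dict[str, tuple[float, float]] = field(default_factory=dict)  # param -> (p, q)
    gamma: dict[str, tuple[float, float]] = field(default_factory=dict)  # param -> (a, b)


@dataclass
class RelabelResult:
    table: pd.DataFrame
    labels: np.ndarray
    n_iter: int
    objective_path: list[float]
    algorithm: str


# ---------------------------------------------------------------------------
# estimators


class _RelabelerBase(BaseEstimator, TransformerMixin):
    def __init__(self, mappings=None, column_map=None, max_iter=1000):
        self.mappings = mappings
        self.column_map = column_map
        self.max_iter = max_iter

    def _setup(self, X: pd.DataFrame):
        if not self.mappings or not self.mappings[0].is_identity:
            raise ValueError("mappings must be a transform list whose first entry is the identity")
        params = _mapping_params(self.mappings)
        cols = _columns_for(params, self.column_map)
        M = _check_table(X, cols)
        return params, cols, M

    def _apply(self, X: pd.DataFrame, z: np.ndarray) -> pd.DataFrame:
        """Row-wise apply mapping[z]; columns outside the event untouched."""
        params, cols, M = self._setup(X)
        imgs = _images(M, self.mappings, params)
        out = X.copy()
        pos = imgs[z, np.arange(len(z))]
        for j, c in enumerate(cols):
            out[c] = pos[:, j]
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def predict(self, X) -> np.ndarray:
        """Transform indicator per row of X under the fitted criterion."""
        return self._assign(X)


class CoGRelabeler(_RelabelerBase):
    """Center-of-gravity relabeler (CoG0, or CoGN when ``normalized``).

    Fitted attributes: ``labels_`` (transform index per training row),
    ``center_`` (mean of the event parameters over the final
    positions), ``variance_`` (CoGN weights, None for CoG0),
    ``n_iter_``, ``objective_path_`` (sum of squared distances after
    each reassignment; nonincreasing for CoG0).
    """

    def __init__(self, mappings=None, normalized=False, column_map=None, max_iter=1000):
        super().__init__(mappings=mappings, column_map=column_map, max_iter=max_iter)
        self.normalized = normalized

    def fit(self, X, y=None):
        params, cols, M = self._setup(X)
        imgs = _images(M, self.mappings, params)
        N = M.shape[0]
        rows = np.arange(N)
        z = init_labels(X, self.mappings, self.column_map)
        self.objective_path_ = []
        for it in range(1, self.max_iter + 1):
            pos = imgs[z, rows]
            mu = pos.mean(axis=0)
            if self.normalized:
                var = pos.var(axis=0)
                w = 1.0 / np.maximum(var, 1e-30)
            else:
                var, w = None, 1.0
            d2 = ((imgs - mu) ** 2 * w).sum(axis=2)  # (T, N)
            z_new = _keep_current_argbest(d2, z, maximize=False)
            self.objective_path_.append(float(d2[z_new, rows].sum()))
            if np.array_equal(z_new, z):
                z = z_new
                break
            z = z_new
        else:
            it = self.max_iter
            warnings.warn(f"CoG relabeler did not settle within max_iter={self.max_iter}")
        self.labels_ = z
        self.center_ = mu
        self.variance_ = var
        self.n_iter_ = it
        self.columns_ = cols
        self.params_ = params
        return self

    def _assign(self, X) -> np.ndarray:
        params, cols, M = self._setup(X)
        imgs = _images(M, self.mappings, params)
        w = 1.0 if self.variance_ is None else 1.0 / np.maximum(self.variance_, 1e-30)
        d2 = ((imgs - self.center_) ** 2 * w).sum(axis=2)
        z0 = init_labels(X, self.mappings, self.column_map)
        return _keep_current_argbest(d2, z0, maximize=False)

    def transform(self, X):
        return self._apply(X, self._assign(X))


class BetaGammaRelabeler(_RelabelerBase):
    """Beta-gamma relabeler: ML beta fits for phi columns, gamma fits
    for theta columns, alternated with per-row best-transform selection.

    Fitted attributes: ``labels_``, ``fit_`` (:class:`BetaGammaFit`),
    ``n_iter_``, ``objective_path_`` (log likelihood after each half
    step; nondecreasing).
    """

    def fit(self, X, y=None):
        params, cols, M = self._setup(X)
        imgs = _images(M, self.mappings, params)
        phi = _phi_mask(params)
        N = M.shape[0]
        rows = np.arange(N)
        z = init_labels(X, self.mappings, self.column_map)
        self.objective_path_ = []
        for it in range(1, self.max_iter + 1):
            pos = imgs[z, rows]
            fit = _fit_columns(pos, params, phi)
            ll = _loglik_matrix(imgs, params, phi, fit)  # (T, N)
            self.objective_path_.append(float(ll[z, rows].sum()))
            z_new = _keep_current_argbest(ll, z, maximize=True)
            self.objective_path_.append(float(ll[z_new, rows].sum()))
            if np.array_equal(z_new, z):
                z = z_new
                break
            z = z_new
        else:
            it = self.max_iter
            warnings.warn(f"beta-gamma relabeler did not settle within max_iter={self.max_iter}")
        self.labels_ = z
        self.fit_ = fit
        self.n_iter_ = it
        self.columns_ = cols
        self.params_ = params
        return self

    def _assign(self, X) -> np.ndarray:
        params, cols, M = self._setup(X)
        imgs = _images(M, self.mappings, params)
        ll = _loglik_matrix(imgs, params, _phi_mask(params), self.fit_)
        z0 = init_labels(X, self.mappings, self.column_map)
        return _keep_current_argbest(ll, z0, maximize=True)

    def transform(self, X):
        return self._apply(X, self._assign(X))


# ---------------------------------------------------------------------------
# beta / gamma maximum likelihood


def fit_beta_ml(values, eps: float = PHI_CLAMP) -> tuple[float, float]:
    """ML estimates (p, q) of a beta density from a sample in (0, 1).

    Values are clamped to [eps, 1 - eps] before fitting so boundary
    draws keep the log likelihood finite.  The likelihood depends on the
    data only through mean(log x) and mean(log(1 - x)); it is maximized
    by BFGS on (log p, log q) from a moment-matching start.
    """
    x = np.clip(np.asarray(values, dtype=float), eps, 1.0 - eps)
    if x.size < 2 or np.all(x == x[0]):
        raise ValueError("beta MLE needs at least two distinct values")
    s1 = float(np.mean(np.log(x)))
    s2 = float(np.mean(np.log1p(-x)))
    m, v = float(x.mean()), float(x.var())
    v = min(max(v, 1e-12), m * (1.0 - m) * (1.0 - 1e-9))
    conc = m * (1.0 - m) / v - 1.0
    start = np.log([max(m * conc, 1e-3), max((1.0 - m) * conc, 1e-3)])

    def negloglik(u):
        p, q = np.exp(u)
        f = special.betaln(p, q) - (p - 1.0) * s1 - (q - 1.0) * s2
        dp = special.digamma(p) - special.digamma(p + q)
        dq = special.digamma(q) - special.digamma(p + q)
        return f, np.array([p * (dp - s1), q * (dq - s2)])

    res = optimize.minimize(negloglik, start, jac=True, method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 500})
    p, q = np.exp(res.x)
    return float(p), float(q)


def fit_gamma_ml(values) -> tuple[float, float]:
    """ML estimates (a, b) of a gamma density (shape, rate) from a
    positive sample.

    The rate is profiled out exactly (b = a / mean, the first-order
    condition, so the fitted mean a/b equals the sample mean), leaving
    the one-dimensional equation log a - psi(a) = log(mean) - mean(log)
    solved by Newton from the closed-form starting value.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("gamma MLE needs strictly positive values")
    if x.size < 2 or np.all(x == x[0]):
        raise ValueError("gamma MLE needs at least two distinct values")
    m = float(x.mean())
    s = float(np.log(m) - np.mean(np.log(x)))
    s = max(s, 1e-12)
    a = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(100):
        f = np.log(a) - special.digamma(a) - s
        fp = 1.0 / a - special.polygamma(1, a)
        step = f / fp
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < 1e-12 * a:
            a = a_new
            break
        a = a_new
    return float(a), float(a / m)


def _fit_columns(pos: np.ndarray, params: list[str], phi: np.ndarray) -> BetaGammaFit:
    fit = BetaGammaFit()
    for j, prm in enumerate(params):
        col = pos[:, j]
        if phi[j]:
            fit.beta[prm] = fit_beta_ml(col)
        else:
            fit.gamma[prm] = fit_gamma_ml(np.maximum(col, THETA_CLAMP))
    return fit


def _loglik_matrix(imgs: np.ndarray, params: list[str], phi: np.ndarray,
                   fit: BetaGammaFit) -> np.ndarray:
    """(T, N) log density of each transform image under the fit."""
    T, N, _ = imgs.shape
    ll = np.zeros((T, N))
    for j, prm in enumerate(params):
        col = imgs[:, :, j]
        if phi[j]:
            p, q = fit.beta[prm]
            xc = np.clip(col, PHI_CLAMP, 1.0 - PHI_CLAMP)
            ll += (p - 1.0) * np.log(xc) + (q - 1.0) * np.log1p(-xc) - special.betaln(p, q)
        else:
            a, b = fit.gamma[prm]
            xc = np.maximum(col, THETA_CLAMP)
            ll += a * np.log(b) - special.gammaln(a) + (a - 1.0) * np.log(xc) - b * xc
    return ll


def beta_gamma_loglik(
    table: pd.DataFrame,
    labels: np.ndarray,
    fit: BetaGammaFit,
    mappings: list[TowerMapping],
    column_map: dict[str, str] | None = None,
) -> float:
    """Total log likelihood sum_t log f(z_t(Theta_t); omega) of the
    transformed draws under independent beta (phi) and gamma (theta)
    densities (clamping keeps it finite)."""
    params = _mapping_params(mappings)
    cols = _columns_for(params, column_map)
    M = _check_table(table, cols)
    imgs = _images(M, mappings, params)
    ll = _loglik_matrix(imgs, params, _phi_mask(params), fit)
    z = np.asarray(labels)
    if len(z) != M.shape[0] or np.any(z >= len(mappings)):
        raise ValueError("invalid label vector")
    return float(ll[z, np.arange(M.shape[0])].sum())


# ---------------------------------------------------------------------------
# functional wrappers and whole-model driver


def cog_relabel(
    table: pd.DataFrame,
    mappings: list[TowerMapping],
    normalized: bool = False,
    column_map: dict[str, str] | None = None,
    max_iter: int = 1000,
) -> RelabelResult:
    est = CoGRelabeler(mappings=mappings, normalized=normalized,
                       column_map=column_map, max_iter=max_iter).fit(table)
    return RelabelResult(
        table=est._apply(table, est.labels_),
        labels=est.labels_,
        n_iter=est.n_iter_,
        objective_path=est.objective_path_,
        algorithm="cogn" if normalized else "cog0",
    )


def beta_gamma_relabel(
    table: pd.DataFrame,
    mappings: list[TowerMapping],
    column_map: dict[str, str] | None = None,
    max_iter: int = 1000,
) -> RelabelResult:
    est = BetaGammaRelabeler(mappings=mappings, column_map=column_map,
                             max_iter=max_iter).fit(table)
    return RelabelResult(
        table=est._apply(table, est.labels_),
        labels=est.labels_,
        n_iter=est.n_iter_,
        objective_path=est.objective_path_,
        algorithm="betagamma",
    )


@dataclass
class RelabelAllResult:
    table: pd.DataFrame
    passes: list[tuple[tuple[str, ...], RelabelResult]]
    nonsister_events: list[tuple[str, str]]


def relabel_all(
    table: pd.DataFrame,
    model: MSciModel,
    algorithm: str = "betagamma",
    column_map: dict[str, str] | None = None,
    max_iter: int = 1000,
) -> RelabelAllResult:
    """Apply the chosen algorithm once per sister BDI event (once per
    stacked double-BDI pair, with four transforms), in ascending event
    time, ties by node label.  Nonsister events are reported, not
    relabeled (a fixed-model MCMC visits a single model variant)."""
    if algorithm not in ("cog0", "cogn", "betagamma"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    events = detect_bdi_events(model)
    stacked = find_stacked_pairs(model, events)
    in_stack = {id(e) for pair in stacked for e in pair}
    groups: list[tuple[float, tuple[str, ...], list[TowerMapping]]] = []
    for e in events:
        if e.sister and id(e) not in in_stack:
            groups.append((e.time, e.nodes, [identity_mapping(), single_bdi_mapping(e)]))
    for lo, up in stacked:
        groups.append((lo.time, lo.nodes + up.nodes, double_bdi_mappings(lo, up)))
    groups.sort(key=lambda g: (g[0], g[1]))

    passes = []
    current = table
    for _, ids, mappings in groups:
        if algorithm == "betagamma":
            res = beta_gamma_relabel(current, mappings, column_map, max_iter)
        else:
            res = cog_relabel(current, mappings, algorithm == "cogn", column_map, max_iter)
        passes.append((ids, res))
        current = res.table
    nonsister = [e.nodes for e in events if not e.sister and id(e) not in in_stack]
    return RelabelAllResult(table=current, passes=passes, nonsister_events=nonsister)


def relabel_accuracy(z_est, z_true) -> float:
    """Fraction of agreeing labels, maximized over the global tower
    relabelings (mirror towers are equally correct answers).

    For two towers the relabelings are identity and the global flip; for
    four (double-BDI) they are the Klein-group translations, i.e. XOR of
    the tower code with a fixed element.
    """
    a = np.asarray(z_est, dtype=int)
    b = np.asarray(z_true, dtype=int)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    t = int(max(a.max(initial=0), b.max(initial=0))) + 1
    t = 2 if t <= 2 else 4
    return max(float(np.mean((a ^ g) == b)) for g in range(t))
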