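"""Atom-packing analysis with concentric sampling spheres.

Around each pore point p the atomic environment is sampled with K_alpha
concentric spheres of radii l_alpha = D(p) + alpha*(L(p)-D(p))/K_alpha.
The atomic cumulative distribution function N(p, l) (atoms within radius l,
boundary inclusive) follows a sigmoid profile that is fitted with four
re-parametrised growth models — Logistic, Gompertz, modified Gompertz and
Richards — selected by minimal AIC.  The selected model yields the
lag/inflection/asymptote partition: s(p) ends the lag domain, the inflection
scale xi(p) is where the radial distribution function peaks (at the maximum
packing rate t(p)), and o(p) = s(p) + A(p)/t(p) starts the asymptote domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .annotation import SegmentAnnotation
from .pore_geometry import PorePoint
from .structure_io import Structure

_E = float(np.e)
FAMILIES = ("logistic", "gompertz", "modified_gompertz", "richards")


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# sampling grid and CDF
# ---------------------------------------------------------------------------
@dataclass
class SamplingGrid:
    """Concentric-sphere radii l_alpha(p), alpha = 1..K (Å)."""

    p_index: int
    radii: np.ndarray

    @property
    def k_alpha(self) -> int:
        return len(self.radii)


@dataclass
class CdfProfile:
    """Atom counts N(p, l_alpha) and the N_c-normalised profile."""

    p_index: int
    counts: np.ndarray
    n_total: int

    @property
    def normalized(self) -> np.ndarray:
        return self.counts / self.n_total


def sampling_radii(p: PorePoint, k_alpha: int = 800) -> SamplingGrid:
    """Arithmetic progression of sphere radii from just above D(p) to L(p)."""
    if k_alpha < 2:
        raise ValueError("k_alpha must be >= 2")
    D = p.nearest_center_distance
    L = p.outer_radius
    if L <= D:
        raise ValueError(f"degenerate geometry at pore point {p.index}: L={L} <= D={D}")
    alpha = np.arange(1, k_alpha + 1, dtype=float)
    radii = D + alpha * (L - D) / k_alpha
    radii[-1] = L  # exact endpoint
    return SamplingGrid(p_index=p.index, radii=radii)


def atomic_cdf(structure: Structure, p: PorePoint, grid: SamplingGrid) -> CdfProfile:
    """N(p, l) = #{i : ||c_i - p|| <= l}; an atom exactly on the sphere counts."""
    d = np.sort(np.linalg.norm(structure.coords - p.position, axis=1))
    counts = np.searchsorted(d, grid.radii, side="right")
    return CdfProfile(p_index=p.index, counts=counts.astype(np.int64), n_total=structure.n_atoms)


# ---------------------------------------------------------------------------
# sigmoid model family
# ---------------------------------------------------------------------------
def _safe_exp(x: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(x, -745.0, 700.0))


def logistic_model(l, A, t, s):
    return A / (1.0 + _safe_exp(4.0 * t / A * (s - l) + 2.0))


def gompertz_model(l, A, t, s):
    return A * _safe_exp(-_safe_exp(_E * t / A * (s - l) + 1.0))


def modified_gompertz_model(l, A, t, s, w, l_shift):
    return gompertz_model(l, A, t, s) + A * _safe_exp(w * (l - l_shift))


def richards_model(l, A, t, s, q_tilde):
    q = q_tilde
    k = t / A * (1.0 + q) ** (1.0 + 1.0 / q)
    # q * b * exp(-k l) evaluated in log space for stability
    expo = np.log(q) + 1.0 + q + k * (s - np.asarray(l, dtype=float))
    u = _safe_exp(expo)
    return A * (1.0 + u) ** (-1.0 / q)


MODEL_FUNCS = {
    "logistic": logistic_model,
    "gompertz": gompertz_model,
    "modified_gompertz": modified_gompertz_model,
    "richards": richards_model,
}
MODEL_NPARAMS = {"logistic": 3, "gompertz": 3, "modified_gompertz": 5, "richards": 4}


def model_inflection(family: str, params: dict[str, float], l_range: tuple[float, float] | None = None) -> float:
    """Scale xi at which the model's second derivative vanishes (RDF peak)."""
    A, t, s = params["A"], params["t"], params["s"]
    if family == "logistic":
        return s + A / (2.0 * t)
    if family == "gompertz":
        return s + A / (_E * t)
    if family == "richards":
        q = params["q_tilde"]
        k = t / A * (1.0 + q) ** (1.0 + 1.0 / q)
        return s + (1.0 + q) / k
    if family == "modified_gompertz":
        # numeric root of the second derivative, seeded near the Gompertz part
        lo, hi = l_range if l_range is not None else (s, s + 3.0 * A / t)
        grid = np.linspace(lo, hi, 2001)
        y = modified_gompertz_model(grid, A, t, s, params["w_m"], params["l_shift"])
        d2 = np.gradient(np.gradient(y, grid), grid)
        sign = np.sign(d2)
        idx = np.nonzero(np.diff(sign) != 0)[0]
        if len(idx) == 0:
            return s + A / (_E * t)
        guess = s + A / (_E * t)
        best = idx[np.argmin(np.abs(grid[idx] - guess))]
        x0, x1 = grid[best], grid[best + 1]
        y0, y1 = d2[best], d2[best + 1]
        return float(x0 - y0 * (x1 - x0) / (y1 - y0)) if y1 != y0 else float(x0)
    raise ValueError(f"unknown model family {family!r}")


@dataclass
class SigmoidFit:
    """Selected sigmoid fit of the atomic CDF at one pore point.

    Derived quantities: ``xi`` (inflection scale), ``o = s + A/t`` (start of
    the asymptote domain, from t = A/(o - s)).
    """

    p_index: int
    family: str
    A: float
    t: float
    s: float
    q_tilde: float | None
    w_m: float | None
    l_shift: float | None
    xi: float
    o: float
    rss: float
    aic: float
    aic_all: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def params(self) -> dict[str, float]:
        p = {"A": self.A, "t": self.t, "s": self.s}
        if self.q_tilde is not None:
            p["q_tilde"] = self.q_tilde
        if self.w_m is not None:
            p["w_m"] = self.w_m
            p["l_shift"] = self.l_shift
        return p

    def predict(self, l: np.ndarray) -> np.ndarray:
        return MODEL_FUNCS[self.family](np.asarray(l, dtype=float), **self.params)


def _aic(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k


def _initial_guess(l: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    A0 = max(float(np.max(y)), 1e-9)
    dy = np.diff(y) / np.diff(l)
    i = int(np.argmax(dy))
    t0 = max(float(dy[i]), 1e-9)
    s0 = float(0.5 * (l[i] + l[i + 1]) - A0 / (2.0 * t0))
    return A0, t0, s0


def _fit_family(family: str, l: np.ndarray, y: np.ndarray) -> tuple[dict[str, float], float] | None:
    A0, t0, s0 = _initial_guess(l, y)
    span = float(l[-1] - l[0])
    if family in ("logistic", "gompertz"):
        names = ["A", "t", "s"]
        x0 = [A0, t0, s0]
        lo = [1e-9, 1e-9, -np.inf]
        hi = [np.inf, np.inf, np.inf]
    elif family == "richards":
        names = ["A", "t", "s", "q_tilde"]
        x0 = [A0, t0, s0, 1.0]
        lo = [1e-9, 1e-9, -np.inf, 1e-4]
        hi = [np.inf, np.inf, np.inf, 50.0]
    else:  # modified_gompertz
        names = ["A", "t", "s", "w", "l_shift"]
        x0 = [A0, t0, s0, 0.01 / max(span, 1.0), float(l[-1])]
        lo = [1e-9, 1e-9, -np.inf, 1e-12, float(l[0])]
        hi = [np.inf, np.inf, np.inf, 10.0, float(l[-1]) + 10.0 * span]
    func = MODEL_FUNCS[family]

    def residual(x):
        return func(l, *x) - y

    try:
        with np.errstate(all="ignore"):
            res = least_squares(residual, x0, bounds=(lo, hi), method="trf", max_nfev=2000)
    except Exception:
        return None
    if not np.all(np.isfinite(res.x)):
        return None
    rss = float(np.sum(res.fun**2))
    if not np.isfinite(rss):
        return None
    params = dict(zip(names, res.x))
    return params, rss


def fit_sigmoid(
    cdf: CdfProfile,
    grid: SamplingGrid,
    families: tuple[str, ...] = FAMILIES,
    normalized: bool = False,
) -> SigmoidFit:
    """Fit all candidate models by least squares and keep the AIC-minimal one.

    Fitting is on raw counts by default; ``normalized=True`` fits the
    N_c-normalised profile instead (the partition scales s, xi, o are
    unaffected by the vertical rescaling).
    """
    l = np.asarray(grid.radii, dtype=float)
    y = cdf.normalized if normalized else cdf.counts.astype(float)
    if len(l) < 10:
        raise ValueError("need at least 10 grid points to fit")
    # true atom counts are integers and must be a nondecreasing CDF; float
    # series (e.g. noisy synthetic curves) are accepted as-is
    if np.issubdtype(np.asarray(cdf.counts).dtype, np.integer) and np.any(np.diff(cdf.counts) < 0):
        raise ValueError("CDF counts must be nondecreasing")
    n = len(l)
    results: dict[str, tuple[dict[str, float], float, float]] = {}
    aic_all: dict[str, float] = {}
    for family in families:
        out = _fit_family(family, l, y)
        if out is None:
            aic_all[family] = np.inf
            continue
        params, rss = out
        aic = _aic(rss, n, MODEL_NPARAMS[family])
        results[family] = (params, rss, aic)
        aic_all[family] = aic
    if not results:
        return SigmoidFit(
            p_index=cdf.p_index, family="none", A=np.nan, t=np.nan, s=np.nan,
            q_tilde=None, w_m=None, l_shift=None, xi=np.nan, o=np.nan,
            rss=np.nan, aic=np.nan, aic_all=aic_all, converged=False,
        )
    family = min(results, key=lambda f: results[f][2])
    params, rss, aic = results[family]
    mp = {"A": params["A"], "t": params["t"], "s": params["s"]}
    if family == "richards":
        mp["q_tilde"] = params["q_tilde"]
    if family == "modified_gompertz":
        mp["w_m"] = params["w"]
        mp["l_shift"] = params["l_shift"]
    xi = model_inflection(family, mp, l_range=(float(l[0]), float(l[-1])))
    return SigmoidFit(
        p_index=cdf.p_index,
        family=family,
        A=float(params["A"]),
        t=float(params["t"]),
        s=float(params["s"]),
        q_tilde=float(params.get("q_tilde")) if "q_tilde" in params else None,
        w_m=float(params.get("w")) if "w" in params else None,
        l_shift=float(params.get("l_shift")) if "l_shift" in params else None,
        xi=float(xi),
        o=float(params["s"] + params["A"] / params["t"]),
        rss=rss,
        aic=aic,
        aic_all=aic_all,
        converged=True,
    )


# ---------------------------------------------------------------------------
# pore-module / voltage-sensor transition
# ---------------------------------------------------------------------------
@dataclass
class TransitionProfile:
    """Radial scale nu(p) at which the voltage-sensor atom count overtakes
    the pore-module count around p; undefined if it never does."""

    p_index: int
    nu: float
    defined: bool


def pm_vs_transition(
    structure: Structure,
    p: PorePoint,
    grid: SamplingGrid,
    annotation: SegmentAnnotation,
    roles: np.ndarray | None = None,
) -> TransitionProfile:
    """nu(p) = smallest l_alpha with cumulative VS count >= cumulative PM
    count (requiring at least one PM atom inside, so the crossing is a real
    overtake and not the empty-sphere case)."""
    if annotation is None and roles is None:
        raise ValueError("segment annotation required")
    if roles is None:
        roles = annotation.roles(structure)
    d = np.linalg.norm(structure.coords - p.position, axis=1)
    d_pm = np.sort(d[roles == "PM"])
    d_vs = np.sort(d[roles == "VS"])
    if len(d_vs) == 0 or len(d_pm) == 0:
        return TransitionProfile(p_index=p.index, nu=np.nan, defined=False)
    n_pm = np.searchsorted(d_pm, grid.radii, side="right")
    n_vs = np.searchsorted(d_vs, grid.radii, side="right")
    ok = (n_vs >= n_pm) & (n_pm > 0)
    if not ok.any():
        return TransitionProfile(p_index=p.index, nu=np.nan, defined=False)
    return TransitionProfile(p_index=p.index, nu=float(grid.radii[np.argmax(ok)]), defined=True)


# ---------------------------------------------------------------------------
# summary descriptors
# ---------------------------------------------------------------------------
@dataclass
class SummaryDescriptors:
    """Median statistical descriptors over pore points (Å and scaling-index
    units) and the per-alpha 95% band of the normalised CDF."""

    s_median: float
    xi_median: float
    o_median: float
    nu_median: float
    alpha_s: float
    alpha_xi: float
    alpha_o: float
    alpha_nu: float
    band_lo: np.ndarray | None = None
    band_hi: np.ndarray | None = None
    n_converged: int = 0


def _alpha_index(value: float, grid: SamplingGrid) -> float:
    """Fractional scaling index alpha corresponding to a radius on a grid."""
    r = grid.radii
    k = len(r)
    D = r[0] - (r[-1] - r[0]) / (k - 1)  # l_0 = D
    step = (r[-1] - D) / k
    return (value - D) / step


def summarize_profiles(
    fits: list[SigmoidFit],
    transitions: list[TransitionProfile] | None = None,
    grids: list[SamplingGrid] | None = None,
    normalized_cdf: np.ndarray | None = None,
) -> SummaryDescriptors:
    """Medians of s, xi, o (converged fits), nu (defined transitions) and of
    their scaling indices; optional 2.5/97.5 percentile band per alpha of the
    normalised CDF across pore points."""
    good = [f for f in fits if f.converged]
    if not good:
        raise FitError("no converged sigmoid fit; nothing to summarise")
    s_med = float(np.median([f.s for f in good]))
    xi_med = float(np.median([f.xi for f in good]))
    o_med = float(np.median([f.o for f in good]))
    nu_vals = [t.nu for t in (transitions or []) if t.defined]
    nu_med = float(np.median(nu_vals)) if nu_vals else np.nan
    a_s = a_xi = a_o = a_nu = np.nan
    if grids is not None:
        by_p = {g.p_index: g for g in grids}
        a_s = float(np.median([_alpha_index(f.s, by_p[f.p_index]) for f in good if f.p_index in by_p]))
        a_xi = float(np.median([_alpha_index(f.xi, by_p[f.p_index]) for f in good if f.p_index in by_p]))
        a_o = float(np.median([_alpha_index(f.o, by_p[f.p_index]) for f in good if f.p_index in by_p]))
        if transitions:
            vals = [
                _alpha_index(t.nu, by_p[t.p_index])
                for t in transitions
                if t.defined and t.p_index in by_p
            ]
            a_nu = float(np.median(vals)) if vals else np.nan
    band_lo = band_hi = None
    if normalized_cdf is not None:
        band_lo = np.percentile(normalized_cdf, 2.5, axis=0)
        band_hi = np.percentile(normalized_cdf, 97.5, axis=0)
    return SummaryDescriptors(
        s_median=s_med, xi_median=xi_med, o_median=o_med, nu_median=nu_med,
        alpha_s=a_s, alpha_xi=a_xi, alpha_o=a_o, alpha_nu=a_nu,
        band_lo=band_lo, band_hi=band_hi, n_converged=len(good),
    )
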