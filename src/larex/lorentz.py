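"""Multi-Lorentzian decomposition of Z-spectra.

A measured Z-spectrum of a multi-pool system is modelled as

    Z_fit(d) = 1 - sum_i A_i / (1 + ((d - c_i) / (W_i / 2))^2)

one Lorentzian line per pool (water, amide, hydroxyl, two NOE pools and the
semisolid MT pool), with box constraints on every amplitude, width (FWHM,
ppm) and center.  The fit minimizes an arctangent-based loss with a
gradient-based sequential-quadratic-programming optimizer.  After fitting,
the centers are snapped back to the nominal pool offsets ("re-centering")
and a corrected two-pool spectrum -- water plus one target pool -- is
synthesized; that spectrum feeds the relaxation-compensated omega-plot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "LorentzComponent",
    "LorentzFitResult",
    "POOL_ORDER",
    "default_fit_config",
    "lorentzian",
    "model_spectrum",
    "loss",
    "fit_multipool",
    "recenter",
    "synthesize_two_pool",
]

POOL_ORDER = ("water", "amide", "hydroxyl", "noe1", "noe2", "mt")

#: Start values and box constraints (A, W, center) per component, plus the
#: nominal chemical-shift offset the center is snapped back to.
_DEFAULT_CONFIG = {
    "water": dict(A=(0.85, 0.5, 1.1), W=(2.0, 1.0, 6.0), c=(0.0, -0.5, 0.5), nominal=0.0),
    "amide": dict(A=(0.01, 0.0, 0.1), W=(1.0, 0.2, 3.0), c=(3.5, 3.0, 4.0), nominal=3.5),
    "hydroxyl": dict(A=(0.01, 0.0, 0.1), W=(1.0, 0.5, 2.0), c=(1.0, 0.6, 1.4), nominal=1.0),
    "noe1": dict(A=(0.001, 0.0, 0.1), W=(1.0, 0.5, 3.5), c=(-1.6, -2.5, -0.5), nominal=-1.6),
    "noe2": dict(A=(0.03, 0.0, 0.2), W=(1.0, 0.5, 4.0), c=(-3.5, -5.0, -3.0), nominal=-3.5),
    "mt": dict(A=(0.1, 0.0, 0.5), W=(10.0, 8.0, 20.0), c=(-2.3, -3.0, -2.0), nominal=-2.3),
}

LOSS_VARIANTS = ("arctan-elementwise", "literal", "arctan-mse")


@dataclass(frozen=True)
class LorentzComponent:
    """One fitted Lorentzian line: amplitude, FWHM (ppm) and center (ppm)."""

    name: str
    A: float
    W: float
    center_ppm: float
    nominal_ppm: float

    def __call__(self, delta_ppm):
        return lorentzian(delta_ppm, self.A, self.W, self.center_ppm)


@dataclass(frozen=True)
class LorentzFitResult:
    """Outcome of a constrained multi-Lorentzian fit."""

    components: tuple[LorentzComponent, ...]
    loss: float
    iterations: int
    converged: bool
    residuals: np.ndarray
    offsets_ppm: np.ndarray
    loss_variant: str
    recentered: bool = False
    original_centers: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> LorentzComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def model(self, delta_ppm):
        """Evaluate the full fitted model 1 - sum of components."""
        d = np.asarray(delta_ppm, float)
        return 1.0 - sum(c(d) for c in self.components)


def default_fit_config() -> dict:
    """Deep copy of the shipped start/bound configuration."""
    return {k: dict(v) for k, v in _DEFAULT_CONFIG.items()}


def load_fit_config(path) -> dict:
    """Load a start/bound configuration from YAML or JSON.

    The file maps component names to ``{A: [start, lower, upper],
    W: [...], c: [...], nominal: <ppm>}``; unknown components are rejected,
    missing ones fall back to the shipped defaults.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = default_fit_config()
    unknown = set(raw) - set(cfg)
    if unknown:
        raise ValueError(f"unknown Lorentzian components {sorted(unknown)}")
    for name, entry in raw.items():
        for key in ("A", "W", "c"):
            if key in entry:
                vals = entry[key]
                if len(vals) != 3:
                    raise ValueError(f"{name}.{key}: need [start, lower, upper]")
                cfg[name][key] = tuple(float(v) for v in vals)
        if "nominal" in entry:
            cfg[name]["nominal"] = float(entry["nominal"])
    return cfg


def save_fit_config(path, config: dict | None = None) -> None:
    """Write a configuration (default: the shipped one) as YAML."""
    import yaml

    cfg = config or default_fit_config()
    doc = {
        name: {
            "A": list(entry["A"]), "W": list(entry["W"]),
            "c": list(entry["c"]), "nominal": entry["nominal"],
        }
        for name, entry in cfg.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def lorentzian(delta_ppm, A, W, center_ppm):
    """Lorentzian absorption line with amplitude ``A`` and FWHM ``W`` (ppm)."""
    if np.any(np.asarray(W) <= 0):
        raise ValueError("width W must be positive")
    d = np.asarray(delta_ppm, float)
    out = A / (1.0 + ((d - center_ppm) / (W / 2.0)) ** 2)
    return float(out) if np.isscalar(delta_ppm) else out


def model_spectrum(delta_ppm, params: np.ndarray) -> np.ndarray:
    """Z model for a flat parameter vector [(A, W, c) x 6 pools]."""
    d = np.asarray(delta_ppm, float)
    Z = np.ones_like(d)
    for i in range(len(params) // 3):
        A, W, c = params[3 * i : 3 * i + 3]
        Z -= A / (1.0 + ((d - c) / (W / 2.0)) ** 2)
    return Z


def loss(residuals, variant: str = "arctan-elementwise") -> float:
    """Arctangent fit loss.

    The default applies arctan per residual before squaring and averaging,
    which keeps the loss zero only at a perfect fit while preserving the
    soft gradient of the arctangent away from zero.  The "literal" variant
    squares the arctangent of the *signed mean* residual; it is degenerate
    (positive and negative residuals cancel) and only kept for comparison.
    "arctan-mse" applies arctan to the mean squared residual.
    """
    r = np.asarray(residuals, float)
    if not np.all(np.isfinite(r)):
        raise ValueError("residuals must be finite")
    if variant == "arctan-elementwise":
        return float(np.mean(np.arctan(r) ** 2))
    if variant == "literal":
        return float(np.arctan(np.mean(r)) ** 2)
    if variant == "arctan-mse":
        return float(np.arctan(np.mean(r**2)))
    raise ValueError(f"unknown loss variant {variant!r}")


def _pack(config: dict) -> tuple[np.ndarray, list[tuple[float, float]]]:
    x0, bounds = [], []
    for name in POOL_ORDER:
        for key in ("A", "W", "c"):
            start, lo, hi = config[name][key]
            if not (lo <= start <= hi):
                raise ValueError(f"{name}.{key}: start {start} outside [{lo}, {hi}]")
            x0.append(start)
            bounds.append((lo, hi))
    return np.array(x0), bounds


def fit_multipool(
    offsets_ppm,
    Z,
    config: dict | None = None,
    loss_variant: str = "arctan-elementwise",
    multistart: int = 1,
    seed: int = 0,
    maxiter: int = 400,
) -> LorentzFitResult:
    """Fit the six-component Lorentzian model to one Z-spectrum.

    ``multistart > 1`` adds jittered start vectors (uniform within a 25%
    band of the box around the configured start, from a generator seeded
    with ``seed``); the start with the best final loss wins.  The result is
    deterministic for fixed inputs and seed.  Optimizer failure is reported
    through ``converged=False`` with the best parameters found, never as an
    exception.
    """
    offsets = np.asarray(offsets_ppm, float)
    y = np.asarray(Z, float)
    if offsets.shape != y.shape:
        raise ValueError("offsets and Z must have identical shape")
    cfg = config or _DEFAULT_CONFIG
    x0, bounds = _pack(cfg)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def objective(x):
        return loss(y - model_spectrum(offsets, x), loss_variant)

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, multistart - 1)):
        jitter = rng.uniform(-0.25, 0.25, size=x0.size) * (hi - lo)
        starts.append(np.clip(x0 + jitter, lo, hi))

    best = None
    for start in starts:
        res = minimize(
            objective,
            start,
            method="SLSQP",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res

    x = np.clip(best.x, lo, hi)  # guard round-off at active bounds
    comps = tuple(
        LorentzComponent(
            name,
            A=float(x[3 * i]),
            W=float(x[3 * i + 1]),
            center_ppm=float(x[3 * i + 2]),
            nominal_ppm=cfg[name]["nominal"],
        )
        for i, name in enumerate(POOL_ORDER)
    )
    residuals = y - model_spectrum(offsets, x)
    return LorentzFitResult(
        components=comps,
        loss=float(best.fun),
        iterations=int(best.nit),
        converged=bool(best.success),
        residuals=residuals,
        offsets_ppm=offsets,
        loss_variant=loss_variant,
    )


def recenter(result: LorentzFitResult) -> LorentzFitResult:
    """Snap every fitted center back to its nominal pool offset.

    Amplitudes and widths are untouched; the fitted centers are kept in
    ``original_centers``.  After re-centering, the synthesized two-pool
    spectrum carries the CEST effects at exactly the assumed offsets.
    """
    originals = {c.name: c.center_ppm for c in result.components}
    comps = tuple(replace(c, center_ppm=c.nominal_ppm) for c in result.components)
    return replace(
        result, components=comps, recentered=True, original_centers=originals
    )


def synthesize_two_pool(
    result: LorentzFitResult,
    target: str = "hydroxyl",
    offsets_ppm=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrected two-pool Z-spectrum: water line plus one metabolite line.

    Returns ``(offsets, Z_corr)`` with ``Z_corr = 1 - L_water - L_target``
    evaluated on ``offsets_ppm`` (default: the grid the fit used).  The fit
    must be re-centered first so the target sits at its nominal offset.
    """
    names = [c.name for c in result.components]
    if target not in names:
        raise ValueError(f"unknown target pool {target!r}; have {names}")
    if target == "water":
        raise ValueError("target must be a solute pool, not water")
    if not result.recentered:
        raise ValueError("re-center the fit before synthesizing (see recenter())")
    grid = result.offsets_ppm if offsets_ppm is None else np.asarray(offsets_ppm, float)
    Z = 1.0 - result["water"](grid) - result[target](grid)
    return grid, Z
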