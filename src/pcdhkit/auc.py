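"""Sedimentation-equilibrium forward model, global association-model fitting,
and oligomeric-state classification.

Model
-----
At sedimentation equilibrium a buoyant species of monomer mass M develops an
exponential radial concentration profile.  With the reduced buoyant term

    sigma1 = M (1 - vbar rho) omega^2 / (2 R T)        [cm^-2]

an n-mer obeys  c_n(r) = c_n(r_ref) * exp(n sigma1 (r^2 - r_ref^2)).  The
species are coupled by mass action at the reference radius:

* monomer-dimer:          c2 = c1^2 / K_D
* monomer-dimer-tetramer: additionally c4 = c2^2 / K_24
* isodesmic:              c_{n+1} = c_n c1 / K_I for all n (equal stepwise
  constant), giving a closed-form geometric-series signal sum valid for
  c1/K_I < 1.

All K's are molar dissociation constants on the monomer concentration scale
and are reported in μM.  The recorded absorbance is the extinction-weighted,
path-length-scaled total monomer-equivalent concentration plus a per-channel
baseline:  A(r) = eps * l * sum_n n c_n(r) + E0.

Fitting
-------
``global_fit`` runs nonlinear least squares jointly over all scans: the
association constants are shared, each scan has a free reference (monomer)
concentration, and each channel a free baseline.  Multi-start initialisation
over a log-spaced K grid with a fixed seed makes the fit deterministic.
Model selection in ``classify_oligomer`` uses corrected Akaike information
on the pooled residuals; a dimer-like dataset whose isodesmic constant is
less than twice its dimer dissociation constant is flagged non-specific.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConvergenceError, ParameterError, PhysicsError

R_GAS = 8.314462618e7  # erg / (mol K)

MODEL_KINDS = ("single", "monomer_dimer", "monomer_dimer_tetramer", "isodesmic")


@dataclass(frozen=True)
class SpeciesParams:
    monomer_mass: float  # Da
    vbar: float  # mL/g
    solvent_density: float  # g/mL
    extinction: float  # AU cm^-1 per mol/L (280 nm)
    path_length: float = 1.2  # cm

    def __post_init__(self):
        if self.monomer_mass <= 0:
            raise PhysicsError(f"monomer mass must be positive, got {self.monomer_mass}")
        if not 0.0 < self.vbar * self.solvent_density < 1.0:
            raise PhysicsError(
                f"non-buoyant species: vbar*rho = {self.vbar * self.solvent_density:.3f}"
            )
        if self.extinction <= 0:
            raise PhysicsError("extinction must be positive")

    def sigma1(self, speed_rpm: float, temperature: float) -> float:
        """Reduced buoyant term sigma1 = M(1-vbar rho)omega^2/(2RT) in cm^-2."""
        omega = 2.0 * math.pi * speed_rpm / 60.0
        return (
            self.monomer_mass
            * (1.0 - self.vbar * self.solvent_density)
            * omega**2
            / (2.0 * R_GAS * temperature)
        )


@dataclass
class EquilibriumScan:
    radius: np.ndarray  # cm, strictly increasing
    absorbance: np.ndarray  # AU
    speed: float  # rpm
    temperature: float = 298.15  # K
    channel: str = "A"
    reference_radius: float | None = None  # defaults to radius[0]

    def __post_init__(self):
        self.radius = np.asarray(self.radius, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.radius.ndim != 1 or np.any(np.diff(self.radius) <= 0):
            raise ParameterError("radius grid must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ParameterError("absorbance contains non-finite values")
        if self.reference_radius is None:
            self.reference_radius = float(self.radius[0])


@dataclass
class AssociationModel:
    kind: str  # one of MODEL_KINDS
    kd: float | None = None  # μM, monomer-dimer
    k24: float | None = None  # μM, dimer-tetramer
    ki: float | None = None  # μM, isodesmic stepwise

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ParameterError(f"unknown model kind {self.kind!r}")
        for name, val in (("kd", self.kd), ("k24", self.k24), ("ki", self.ki)):
            if val is not None and val <= 0:
                raise PhysicsError(f"{name} must be positive, got {val}")
        if self.kind == "monomer_dimer" and self.kd is None:
            raise ParameterError("monomer_dimer model requires kd")
        if self.kind == "monomer_dimer_tetramer" and (self.kd is None or self.k24 is None):
            raise ParameterError("monomer_dimer_tetramer model requires kd and k24")
        if self.kind == "isodesmic" and self.ki is None:
            raise ParameterError("isodesmic model requires ki")


@dataclass
class FitResult:
    model_kind: str
    parameters: dict[str, float]  # fitted K's in μM, baselines in AU
    stderr: dict[str, float]
    rms: float
    n_points: int
    n_parameters: int
    classification: str | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def aicc(self) -> float:
        n, k = self.n_points, self.n_parameters
        rss = self.rms**2 * n
        aic = n * math.log(max(rss / n, 1e-300)) + 2 * k
        denom = n - k - 1
        return aic + (2 * k * (k + 1) / denom if denom > 0 else math.inf)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def _signal_profile(
    model: AssociationModel,
    species: SpeciesParams,
    c1_ref: float,
    radius: np.ndarray,
    speed: float,
    temperature: float,
    reference_radius: float,
) -> np.ndarray:
    """Monomer-equivalent signal (AU, baseline-free) on the radius grid."""
    sigma = species.sigma1(speed, temperature)
    x = np.exp(sigma * (radius**2 - reference_radius**2))  # monomer factor
    c1 = c1_ref * x
    micro = 1e-6
    if model.kind == "single":
        total = c1
    elif model.kind == "monomer_dimer":
        kd = model.kd * micro
        total = c1 + 2.0 * c1**2 / kd
    elif model.kind == "monomer_dimer_tetramer":
        kd = model.kd * micro
        k24 = model.k24 * micro
        c2 = c1**2 / kd
        total = c1 + 2.0 * c2 + 4.0 * c2**2 / k24
    elif model.kind == "isodesmic":
        ki = model.ki * micro
        frac = c1 / ki
        if np.any(frac >= 1.0):
            raise PhysicsError(
                "isodesmic series diverges: monomer concentration reaches K_I"
            )
        total = c1 / (1.0 - frac) ** 2  # sum n c1 x^{n-1}
    else:  # pragma: no cover - guarded in AssociationModel
        raise ParameterError(model.kind)
    return species.extinction * species.path_length * total


def _loading_mismatch(
    c1_ref: float,
    model: AssociationModel,
    species: SpeciesParams,
    loading_conc: float,
    radius: np.ndarray,
    speed: float,
    temperature: float,
    reference_radius: float,
) -> float:
    """Sector-averaged total concentration minus the loading concentration."""
    signal = _signal_profile(
        model, species, c1_ref, radius, speed, temperature, reference_radius
    )
    conc = signal / (species.extinction * species.path_length)
    # sector volume element is proportional to r dr
    avg = np.trapezoid(conc * radius, radius) / np.trapezoid(radius, radius)
    return avg - loading_conc


def reference_concentration_for_loading(
    model: AssociationModel,
    species: SpeciesParams,
    loading_conc: float,
    radius: np.ndarray,
    speed: float,
    temperature: float,
    reference_radius: float | None = None,
) -> float:
    """Monomer concentration at the reference radius conserving loading mass."""
    if loading_conc <= 0:
        raise PhysicsError("loading concentration must be positive")
    radius = np.asarray(radius, dtype=float)
    if reference_radius is None:
        reference_radius = float(radius[0])
    hi = loading_conc
    # bracket: the sector average is monotone increasing in c1_ref
    args = (model, species, loading_conc, radius, speed, temperature, reference_radius)
    for _ in range(200):
        try:
            if _loading_mismatch(hi, *args) > 0:
                break
        except PhysicsError:
            hi *= 0.5
            continue
        hi *= 1.5
    lo = loading_conc * 1e-9
    return float(optimize.brentq(_loading_mismatch, lo, hi, args=args, xtol=1e-18))


def simulate_scan(
    model: AssociationModel,
    species: SpeciesParams,
    loading_conc: float,
    radius: np.ndarray,
    speed: float,
    temperature: float = 298.15,
    noise_sd: float = 0.0,
    baseline: float = 0.0,
    channel: str = "A",
    seed: int | None = None,
) -> EquilibriumScan:
    """Synthesise one equilibrium scan with Gaussian noise.

    ``loading_conc`` is the molar total monomer-equivalent concentration of
    the loaded sample; the reference-radius monomer concentration is solved
    so that the sector-integrated mass equals the loading (mass conservation).
    """
    radius = np.asarray(radius, dtype=float)
    c1_ref = reference_concentration_for_loading(
        model, species, loading_conc, radius, speed, temperature
    )
    signal = _signal_profile(
        model, species, c1_ref, radius, speed, temperature, float(radius[0])
    )
    absorbance = signal + baseline
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        absorbance = absorbance + rng.normal(0.0, noise_sd, size=len(radius))
    return EquilibriumScan(
        radius=radius,
        absorbance=absorbance,
        speed=speed,
        temperature=temperature,
        channel=channel,
        reference_radius=float(radius[0]),
    )


# ---------------------------------------------------------------------------
# Scan file I/O (delimited text with small header)
# ---------------------------------------------------------------------------


def write_scan(scan: EquilibriumScan, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# speed_rpm {scan.speed}\n")
        fh.write(f"# temperature_K {scan.temperature}\n")
        fh.write(f"# channel {scan.channel}\n")
        fh.write("radius_cm\tabsorbance_AU\n")
        for r, a in zip(scan.radius, scan.absorbance):
            fh.write(f"{r:.6f}\t{a:.8f}\n")


def read_scan(path: str | Path) -> EquilibriumScan:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) >= 2:
                meta[parts[0]] = parts[1]
    data = pd.read_csv(path, sep="\t", comment="#")
    return EquilibriumScan(
        radius=data["radius_cm"].to_numpy(),
        absorbance=data["absorbance_AU"].to_numpy(),
        speed=float(meta.get("speed_rpm", 0.0)),
        temperature=float(meta.get("temperature_K", 298.15)),
        channel=str(meta.get("channel", "A")),
    )


# ---------------------------------------------------------------------------
# Global fit
# ---------------------------------------------------------------------------

_K_PARAMS = {
    "single": (),
    "monomer_dimer": ("kd",),
    "monomer_dimer_tetramer": ("kd", "k24"),
    "isodesmic": ("ki",),
}


def _unpack(theta, model_kind, scans, channels):
    nk = len(_K_PARAMS[model_kind])
    ks = {name: 10.0 ** theta[i] for i, name in enumerate(_K_PARAMS[model_kind])}
    c_refs = 10.0 ** np.asarray(theta[nk : nk + len(scans)])
    baselines = dict(zip(channels, theta[nk + len(scans):]))
    return ks, c_refs, baselines


def _residuals(theta, model_kind, scans, species, channels):
    ks, c_refs, baselines = _unpack(theta, model_kind, scans, channels)
    try:
        model = AssociationModel(model_kind, **{k: v for k, v in ks.items()})
    except PhysicsError:
        return np.full(sum(len(s.radius) for s in scans), 1e3)
    res = []
    for scan, c_ref in zip(scans, c_refs):
        try:
            pred = _signal_profile(
                model, species, c_ref, scan.radius, scan.speed,
                scan.temperature, scan.reference_radius,
            ) + baselines[scan.channel]
        except PhysicsError:
            pred = np.full(len(scan.radius), 1e3)
        res.append(pred - scan.absorbance)
    return np.concatenate(res)


def global_fit(
    scans: list[EquilibriumScan],
    model_kind: str,
    species: SpeciesParams,
    fit_baselines: bool = True,
    n_starts: int = 4,
    seed: int = 0,
    k_bounds_um: tuple[float, float] = (1e-3, 1e5),
) -> FitResult:
    """Jointly fit an association model to a batch of equilibrium scans.

    Association constants are shared across scans; each scan gets a free
    reference monomer concentration and each channel a free baseline (unless
    ``fit_baselines`` is off).  Initialisation is multi-start over a
    log-spaced K grid (plus a seeded jitter on the remaining starts); the
    best converged start wins.  Raises ConvergenceError if no start converges.
    """
    if model_kind not in MODEL_KINDS:
        raise ParameterError(f"unknown model kind {model_kind!r}")
    if not scans:
        raise ParameterError("need at least one scan")
    channels = sorted({s.channel for s in scans})
    k_names = _K_PARAMS[model_kind]
    nk = len(k_names)
    n_par = nk + len(scans) + (len(channels) if fit_baselines else 0)
    n_pts = sum(len(s.radius) for s in scans)

    # crude scale for initial reference concentrations
    init_crefs = []
    for s in scans:
        amp = max(float(np.percentile(s.absorbance, 10)), 1e-4)
        init_crefs.append(
            math.log10(max(amp / (species.extinction * species.path_length), 1e-12))
        )

    rng = np.random.default_rng(seed)
    lo, hi = math.log10(k_bounds_um[0]), math.log10(k_bounds_um[1])
    if nk:
        k_starts = [np.full(nk, v) for v in np.linspace(lo + 1, hi - 1, max(n_starts, 1))]
    else:
        k_starts = [np.zeros(0)] * max(n_starts, 1)

    lower = np.concatenate([
        np.full(nk, lo), np.full(len(scans), -12.0),
        np.full(len(channels) if fit_baselines else 0, -1.0),
    ])
    upper = np.concatenate([
        np.full(nk, hi), np.full(len(scans), 0.0),
        np.full(len(channels) if fit_baselines else 0, 1.0),
    ])

    best = None
    for i, k0 in enumerate(k_starts):
        jitter = rng.normal(0, 0.1, size=len(init_crefs)) if i else 0.0
        theta0 = np.concatenate([
            k0,
            np.clip(np.asarray(init_crefs) + jitter, -11.9, -0.1),
            np.zeros(len(channels) if fit_baselines else 0),
        ])
        if not fit_baselines:
            def fun(th):
                return _residuals(
                    np.concatenate([th, np.zeros(len(channels))]),
                    model_kind, scans, species, channels,
                )
            bounds = (lower, upper)
        else:
            fun = lambda th: _residuals(th, model_kind, scans, species, channels)  # noqa: E731
            bounds = (lower, upper)
        try:
            sol = optimize.least_squares(
                fun, theta0, bounds=bounds, method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.fun)):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise ConvergenceError(
            f"{model_kind}: no start converged",
            {"n_starts": len(k_starts), "n_points": n_pts},
        )

    theta = best.x if fit_baselines else np.concatenate([best.x, np.zeros(len(channels))])
    ks, c_refs, baselines = _unpack(theta, model_kind, scans, channels)
    rms = float(np.sqrt(2.0 * best.cost / n_pts))

    # parameter standard errors from the Jacobian (linearised)
    stderr: dict[str, float] = {}
    try:
        J = best.jac
        dof = max(n_pts - len(best.x), 1)
        s2 = 2.0 * best.cost / dof
        cov = s2 * np.linalg.pinv(J.T @ J)
        for i, name in enumerate(k_names):
            # delta method: K = 10^theta
            sd_log = math.sqrt(max(cov[i, i], 0.0))
            stderr[name] = ks[name] * math.log(10) * sd_log
    except Exception:
        pass

    params = {name: ks[name] for name in k_names}
    params.update({f"baseline_{ch}": baselines[ch] for ch in channels})
    params.update({f"c_ref_{i}": float(c) for i, c in enumerate(c_refs)})
    return FitResult(
        model_kind=model_kind,
        parameters=params,
        stderr=stderr,
        rms=rms,
        n_points=n_pts,
        n_parameters=n_par,
        diagnostics={"cost": float(best.cost), "status": int(best.status)},
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_oligomer(
    fit_dimer: FitResult,
    fit_isodesmic: FitResult,
    fit_tetramer: FitResult | None = None,
    fit_single: FitResult | None = None,
    tetramer_delta_aicc: float = 10.0,
) -> tuple[str, float | None]:
    """Label a dataset monomer / dimer / tetramer / non-specific.

    Model selection is by corrected Akaike information on the pooled
    residuals of the supplied fits (which must be on the same data).  The
    two-stage (tetramer) model must beat the alternatives decisively
    (delta AICc > ``tetramer_delta_aicc``) to be selected.  When a dimer-like
    model wins, the ratio K_I / K_D below two flags non-specific binding.
    Returns (label, ki_over_kd ratio or None).
    """
    if fit_dimer is None or fit_isodesmic is None:
        raise ParameterError("dimer and isodesmic fits are both required")
    if fit_dimer.n_points != fit_isodesmic.n_points:
        raise ParameterError("fits must be on the same data")
    fits = {"monomer_dimer": fit_dimer, "isodesmic": fit_isodesmic}
    if fit_tetramer is not None:
        fits["monomer_dimer_tetramer"] = fit_tetramer
    if fit_single is not None:
        fits["single"] = fit_single
    aicc = {k: f.aicc for k, f in fits.items()}
    best_kind = min(aicc, key=aicc.get)

    ratio = None
    kd = fit_dimer.parameters.get("kd")
    ki = fit_isodesmic.parameters.get("ki")
    if kd and ki:
        ratio = ki / kd

    if best_kind == "single":
        return "monomer", ratio
    if best_kind == "monomer_dimer_tetramer":
        others = [v for k, v in aicc.items() if k != "monomer_dimer_tetramer"]
        if min(others) - aicc[best_kind] > tetramer_delta_aicc:
            return "tetramer", ratio
        best_kind = min(
            (k for k in aicc if k != "monomer_dimer_tetramer"), key=aicc.get
        )
    # dimer-like winner (monomer_dimer or isodesmic): apply the ratio rule
    if ratio is not None and ratio < 2.0:
        return "non-specific", ratio
    return "dimer", ratio


def fit_report_row(fragment: str, label: str, fit: FitResult,
                   ratio: float | None) -> dict:
    """One row of the oligomeric-state summary table."""
    row = {
        "fragment": fragment,
        "oligomeric_state": label,
        "kd_uM": fit.parameters.get("kd"),
        "k24_uM": fit.parameters.get("k24"),
        "ki_uM": fit.parameters.get("ki"),
        "rms_AU": fit.rms,
    }
    row["ki_over_kd"] = ratio if (ratio is not None and ratio < 2.0) else None
    return row


def fit_to_json(fit: FitResult, path: str | Path) -> None:
    payload = {
        "model_kind": fit.model_kind,
        "parameters": fit.parameters,
        "stderr": fit.stderr,
        "rms": fit.rms,
        "n_points": fit.n_points,
        "n_parameters": fit.n_parameters,
        "classification": fit.classification,
        "aicc": fit.aicc,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
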