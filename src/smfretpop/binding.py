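"""Equilibrium binding analysis: K_D fits, fold changes, ddG, dye labeling.

Two fitting modes are supported, matching how binding is read out:

* ``anisotropy`` — fluorescence anisotropy of a labeled RNA probe titrated
  with protein. Because the probe concentration is typically within an order
  of magnitude of K_D, the bound fraction uses the single-site
  ligand-depletion (quadratic) solution rather than the free-ligand
  hyperbola.
* ``population`` — an open-state (or closed-state) population fraction from
  FRET histogram peak areas at each titrant concentration, fit with a simple
  binding hyperbola F0 + (Fmax-F0)*c/(kd+c).

Fold changes between K_D values convert to binding free-energy differences
via ddG = R*T*ln(K_D_weak/K_D_tight) with R = 1.987e-3 kcal/(mol*K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit

from .errors import InvalidSpectrumError, ParameterError, UnresolvableKdError

#: gas constant, kcal mol^-1 K^-1
R_KCAL = 1.987e-3


@dataclass
class BindingCurve:
    """A titration: concentrations (nM) vs response.

    ``mode`` is "anisotropy" (response = anisotropy, requires
    ``probe_conc``) or "population" (response = a population fraction).
    """

    x: np.ndarray
    y: np.ndarray
    mode: str = "anisotropy"
    probe_conc: float | None = None
    condition: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y):
            raise ParameterError("x and y must have equal length")
        if np.any(self.x < 0):
            raise ParameterError("concentrations must be >= 0")
        if self.mode not in ("anisotropy", "population"):
            raise ParameterError(f"unknown mode {self.mode!r}")


@dataclass
class KdFit:
    """Fitted dissociation constant with endpoints and uncertainties (nM)."""

    kd: float
    kd_stderr: float | None
    endpoints: dict
    residual_rms: float
    mode: str
    params: dict = field(default_factory=dict)


def quadratic_bound_fraction(protein, probe: float, kd: float):
    """Bound probe fraction under single-site binding with ligand depletion.

    FB = ((P+L+Kd) - sqrt((P+L+Kd)^2 - 4*P*L)) / (2*L) with P total protein
    and L total probe concentration. Reduces to P/(P+Kd) for L << Kd.
    """
    p = np.asarray(protein, dtype=float)
    s = p + probe + kd
    disc = s * s - 4.0 * p * probe
    return (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * probe)


def _noise_estimate(y: np.ndarray) -> float:
    """Robust response-noise estimate from lag-1 differences."""
    if len(y) < 3:
        return 0.0
    return float(1.4826 * np.median(np.abs(np.diff(y))) / np.sqrt(2.0))


def fit_kd_anisotropy(curve: BindingCurve) -> KdFit:
    """Fit K_D from an anisotropy titration with the depletion quadratic.

    Raises
    ------
    UnresolvableKdError
        If the response range is smaller than 3x the estimated noise.
    """
    if curve.mode != "anisotropy":
        raise ParameterError("curve.mode must be 'anisotropy'")
    if curve.probe_conc is None or curve.probe_conc <= 0:
        raise ParameterError("anisotropy mode requires probe_conc > 0")
    if len(curve.x) < 5:
        raise ParameterError("need >= 5 concentration points")
    span = float(np.ptp(curve.y))
    noise = _noise_estimate(curve.y)
    if span < 3.0 * noise or span == 0.0:
        raise UnresolvableKdError(
            f"flat titration: response span {span:.3g} < 3x noise {noise:.3g}",
            {"span": span, "noise": noise},
        )
    probe = curve.probe_conc

    def model(x, kd, r_free, r_bound):
        return r_free + (r_bound - r_free) * quadratic_bound_fraction(x, probe, kd)

    mod = lmfit.Model(model)
    pars = mod.make_params(
        kd=dict(value=max(np.median(curve.x), 1e-6), min=1e-9),
        r_free=float(curve.y[np.argmin(curve.x)]),
        r_bound=float(curve.y[np.argmax(curve.x)]),
    )
    res = mod.fit(curve.y, pars, x=curve.x)
    if not res.success:
        raise UnresolvableKdError("anisotropy K_D fit did not converge", {"report": res.message})
    kd = float(res.params["kd"].value)
    err = res.params["kd"].stderr
    return KdFit(
        kd=kd,
        kd_stderr=float(err) if err is not None else None,
        endpoints={
            "r_free": float(res.params["r_free"].value),
            "r_bound": float(res.params["r_bound"].value),
        },
        residual_rms=float(np.sqrt(np.mean(res.residual**2))),
        mode="anisotropy",
        params={k: float(v.value) for k, v in res.params.items()},
    )


def fit_kd_population(curve: BindingCurve) -> KdFit:
    """Fit K_D from a population-fraction titration with a binding hyperbola."""
    if curve.mode != "population":
        raise ParameterError("curve.mode must be 'population'")
    if len(curve.x) < 5:
        raise ParameterError("need >= 5 concentration points")
    span = float(np.ptp(curve.y))
    noise = _noise_estimate(curve.y)
    if span < 3.0 * noise or span == 0.0:
        raise UnresolvableKdError(
            f"flat titration: response span {span:.3g} < 3x noise {noise:.3g}",
            {"span": span, "noise": noise},
        )

    def model(x, kd, f0, fmax):
        return f0 + (fmax - f0) * x / (kd + x)

    mod = lmfit.Model(model)
    pars = mod.make_params(
        kd=dict(value=max(np.median(curve.x), 1e-6), min=1e-9),
        f0=float(curve.y[np.argmin(curve.x)]),
        fmax=float(curve.y[np.argmax(curve.x)]),
    )
    res = mod.fit(curve.y, pars, x=curve.x)
    if not res.success:
        raise UnresolvableKdError("population K_D fit did not converge", {"report": res.message})
    kd = float(res.params["kd"].value)
    err = res.params["kd"].stderr
    return KdFit(
        kd=kd,
        kd_stderr=float(err) if err is not None else None,
        endpoints={
            "f0": float(res.params["f0"].value),
            "fmax": float(res.params["fmax"].value),
        },
        residual_rms=float(np.sqrt(np.mean(res.residual**2))),
        mode="population",
        params={k: float(v.value) for k, v in res.params.items()},
    )


def fold_change(kd_tight: float, kd_weak: float) -> float:
    """Affinity fold change, weak over tight: kd_weak / kd_tight."""
    if kd_tight <= 0 or kd_weak <= 0:
        raise ParameterError("dissociation constants must be > 0")
    return kd_weak / kd_tight


def delta_delta_g(kd_tight: float, kd_weak: float, temperature_k: float = 298.0) -> float:
    """Binding free-energy difference R*T*ln(kd_weak/kd_tight) in kcal/mol."""
    if temperature_k <= 0:
        raise ParameterError("temperature must be > 0 K")
    return R_KCAL * temperature_k * np.log(fold_change(kd_tight, kd_weak))


@dataclass(frozen=True)
class LabelingParams:
    """Extinction coefficients (M^-1 cm^-1) and A280 correction factors.

    ``f280_*`` are the fractions of each dye's visible-band absorbance that
    it contributes at 280 nm (conventional vendor values).
    """

    eps_cy3_550: float = 150_000.0
    eps_cy5_650: float = 250_000.0
    eps_protein_280: float = 17_420.0
    f280_cy3: float = 0.08
    f280_cy5: float = 0.05

    def __post_init__(self):
        if min(self.eps_cy3_550, self.eps_cy5_650, self.eps_protein_280) <= 0:
            raise ParameterError("extinction coefficients must be > 0")
        if not (0.0 <= self.f280_cy3 <= 0.2 and 0.0 <= self.f280_cy5 <= 0.2):
            raise ParameterError("f280 corrections must be in [0, 0.2]")


def labeling_efficiency(
    a550: float, a650: float, a280: float, params: LabelingParams = LabelingParams()
) -> tuple[float, float]:
    """Dyes-per-protein labeling efficiencies from a three-point spectrum.

    The protein concentration is computed from A280 after subtracting each
    dye's 280 nm contribution; each efficiency is the dye concentration
    (A_dye / eps_dye) over the protein concentration.
    """
    if min(a550, a650, a280) < 0:
        raise ParameterError("absorbances must be >= 0")
    a280_corr = a280 - params.f280_cy3 * a550 - params.f280_cy5 * a650
    if a280_corr <= 0:
        raise InvalidSpectrumError(
            f"corrected A280 = {a280_corr:.4g} <= 0: dye absorbance exceeds protein signal"
        )
    c_protein = a280_corr / params.eps_protein_280
    eff_cy3 = (a550 / params.eps_cy3_550) / c_protein
    eff_cy5 = (a650 / params.eps_cy5_650) / c_protein
    return eff_cy3, eff_cy5
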