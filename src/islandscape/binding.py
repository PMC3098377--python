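"""ZF-CxxC-DNA binding: 1:1 Langmuir equilibrium and SPR kinetics.

The domain binds a nonmethylated CpG dinucleotide with a single site, so a
1:1 interaction model suffices: fraction bound follows the hyperbola
c / (c + K_D), sensorgrams follow the standard Langmuir association /
dissociation solution, and K_D = koff / kon. Fitting follows the
statsmodels convention: a model object is built from data and ``fit()``
returns a results object carrying estimates, uncertainties and a
``summary()`` table.

Concentrations are molar internally; K_D is reported in uM.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class KineticParams:
    """1:1 interaction parameters: kon [1/(M s)], koff [1/s], rmax [RU]."""

    kon: float
    koff: float
    rmax: float

    def __post_init__(self) -> None:
        if min(self.kon, self.koff, self.rmax) <= 0:
            raise ValueError("kon, koff and rmax must all be > 0")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant, M."""
        return self.koff / self.kon

    @property
    def kd_uM(self) -> float:
        return self.kd * 1e6


@dataclass
class Sensorgram:
    """One SPR trace: association up to ``t_assoc``, then dissociation."""

    conc: float  # analyte concentration, M
    times: np.ndarray  # seconds from injection start
    response: np.ndarray  # RU
    t_assoc: float


def fraction_bound(conc, kd: float, methylated: bool = False):
    """Equilibrium fraction of probe bound at analyte concentration ``conc``.

    conc / (conc + kd) for a nonmethylated CpG probe. Methylation (or CpG
    mutation) abrogates binding entirely: methylated=True returns 0 at every
    concentration.
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("conc must be >= 0")
    if methylated:
        return np.zeros_like(conc) if conc.ndim else 0.0
    out = conc / (conc + kd)
    return out if conc.ndim else float(out)


def langmuir_response(t, conc: float, params: KineticParams, phase: str, r0: float | None = None):
    """Closed-form 1:1 Langmuir response.

    association: Req (1 - exp(-(kon c + koff) t)), Req = Rmax c / (c + KD);
    dissociation from level r0: r0 exp(-koff t).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if phase == "association":
        req = params.rmax * conc / (conc + params.kd)
        out = req * (1.0 - np.exp(-(params.kon * conc + params.koff) * t))
    elif phase == "dissociation":
        if r0 is None:
            raise ValueError("dissociation phase requires r0")
        out = r0 * np.exp(-params.koff * t)
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return out if t.ndim else float(out)


def _model_curve(theta: np.ndarray, sg: Sensorgram) -> np.ndarray:
    kon, koff, rmax = np.exp(theta)
    kd = koff / kon
    req = rmax * sg.conc / (sg.conc + kd)
    assoc = sg.times <= sg.t_assoc
    out = np.empty_like(sg.response, dtype=float)
    out[assoc] = req * (1.0 - np.exp(-(kon * sg.conc + koff) * sg.times[assoc]))
    r_end = req * (1.0 - np.exp(-(kon * sg.conc + koff) * sg.t_assoc))
    out[~assoc] = r_end * np.exp(-koff * (sg.times[~assoc] - sg.t_assoc))
    return out


class SensorgramKinetics:
    """Global kinetic model over a set of sensorgrams.

    Shared (kon, koff, Rmax) are estimated by nonlinear least squares over
    all curves jointly, in log-parameter space, with a fixed multistart grid
    to dodge local minima.
    """

    def __init__(self, sensorgrams: list[Sensorgram]):
        if len(sensorgrams) < 2:
            raise ValueError("need sensorgrams at >= 2 concentrations")
        for sg in sensorgrams:
            if not (np.any(sg.times <= sg.t_assoc) and np.any(sg.times > sg.t_assoc)):
                raise ValueError("each sensorgram must cover both phases")
        self.sensorgrams = sensorgrams

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [_model_curve(theta, sg) - sg.response for sg in self.sensorgrams]
        )

    def fit(self) -> "KineticsResults":
        r_all = np.concatenate([sg.response for sg in self.sensorgrams])
        if np.ptp(r_all) < 1e-9:
            raise FitError("flat sensorgrams: no binding signal to fit")
        rmax0 = max(float(np.max(np.abs(r_all))) * 1.2, 1e-6)
        best = None
        for kon0 in (1e4, 1e5, 1e6):
            for koff0 in (1e-3, 1e-2, 1e-1):
                theta0 = np.log([kon0, koff0, rmax0])
                try:
                    res = optimize.least_squares(self._residuals, theta0, method="trf")
                except Exception:
                    continue
                if res.success and (best is None or res.cost < best.cost):
                    best = res
        if best is None:
            raise FitError("kinetic fit failed to converge from any start")
        n_obs = r_all.size
        rms = float(np.sqrt(2 * best.cost / n_obs))
        # signal-to-residual sanity: a "fit" explaining nothing is an error
        if rms >= 0.99 * float(np.std(r_all)) and np.ptp(r_all) < 10 * rms:
            raise FitError(f"no resolvable binding signal (residual RMS {rms:.3g})")
        dof = max(n_obs - 3, 1)
        s2 = 2 * best.cost / dof
        jtj = best.jac.T @ best.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
            rel_se = np.sqrt(np.clip(np.diag(cov), 0, None))  # log-scale SE ~ relative SE
        except np.linalg.LinAlgError:
            rel_se = np.full(3, np.inf)
        kon, koff, rmax = np.exp(best.x)
        return KineticsResults(
            params=KineticParams(kon, koff, rmax),
            rel_se={"kon": float(rel_se[0]), "koff": float(rel_se[1]), "rmax": float(rel_se[2])},
            resid_rms=rms,
            n_obs=n_obs,
            n_curves=len(self.sensorgrams),
        )


@dataclass
class KineticsResults:
    params: KineticParams
    rel_se: dict[str, float]
    resid_rms: float
    n_obs: int
    n_curves: int

    @property
    def kd_uM(self) -> float:
        return self.params.kd_uM

    def summary(self) -> str:
        p = self.params
        lines = [
            "1:1 Langmuir kinetic fit",
            "=" * 44,
            f"{'curves':<12}{self.n_curves:>10d}    {'points':<8}{self.n_obs:>10d}",
            f"{'param':<12}{'estimate':>14}{'rel. SE':>14}",
            "-" * 44,
            f"{'kon [1/Ms]':<12}{p.kon:>14.4g}{self.rel_se['kon']:>14.2g}",
            f"{'koff [1/s]':<12}{p.koff:>14.4g}{self.rel_se['koff']:>14.2g}",
            f"{'Rmax [RU]':<12}{p.rmax:>14.4g}{self.rel_se['rmax']:>14.2g}",
            "-" * 44,
            f"{'K_D [uM]':<12}{self.kd_uM:>14.4g}",
            f"{'resid RMS':<12}{self.resid_rms:>14.4g}",
        ]
        return "\n".join(lines)


class SteadyStateIsotherm:
    """Equilibrium-response model Req = Rmax c / (c + K_D)."""

    def __init__(self, concentrations, responses):
        conc = np.asarray(concentrations, dtype=float)
        resp = np.asarray(responses, dtype=float)
        if conc.size < 4:
            raise ValueError("need >= 4 concentrations")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be > 0")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        self.conc, self.resp = conc, resp

    def fit(self) -> "IsothermResults":
        def hyper(c, rmax, kd):
            return rmax * c / (c + kd)

        p0 = [max(float(self.resp.max()), 1e-9), float(np.median(self.conc))]
        popt, pcov = optimize.curve_fit(hyper, self.conc, self.resp, p0=p0, maxfev=20000)
        rmax, kd = float(popt[0]), float(popt[1])
        half = rmax / 2.0
        bracketed = bool(self.resp.min() < half < self.resp.max())
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
        return IsothermResults(
            kd=kd,
            rmax=rmax,
            kd_se=float(se[1]),
            rmax_se=float(se[0]),
            bracketing_warning=not bracketed,
            n_obs=int(self.conc.size),
        )


@dataclass
class IsothermResults:
    kd: float  # M
    rmax: float
    kd_se: float
    rmax_se: float
    bracketing_warning: bool
    n_obs: int

    @property
    def kd_uM(self) -> float:
        return self.kd * 1e6

    def summary(self) -> str:
        lines = [
            "Steady-state 1:1 isotherm fit",
            "=" * 44,
            f"{'points':<12}{self.n_obs:>10d}",
            f"{'K_D [uM]':<12}{self.kd_uM:>14.4g}{self.kd_se * 1e6:>14.2g}",
            f"{'Rmax [RU]':<12}{self.rmax:>14.4g}{self.rmax_se:>14.2g}",
        ]
        if self.bracketing_warning:
            lines.append("warning: concentrations do not bracket the half-max response")
        return "\n".join(lines)


def fit_kinetics(sensorgrams: list[Sensorgram]) -> KineticsResults:
    """Global kinetic fit; see SensorgramKinetics."""
    return SensorgramKinetics(sensorgrams).fit()


def fit_steady_state(concentrations, responses) -> IsothermResults:
    """Steady-state K_D / Rmax fit; see SteadyStateIsotherm."""
    return SteadyStateIsotherm(concentrations, responses).fit()
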