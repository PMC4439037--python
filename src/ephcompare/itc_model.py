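"""One-set-of-sites isothermal titration calorimetry: simulation and fitting.

The model is the single-class independent-sites (Wiseman) isotherm.  With
total cell-species concentration ``M`` and total injectant concentration
``X`` in the cell after injection i (both dilution-corrected), binding
stoichiometry ``n``, association constant ``K_a`` and molar enthalpy ``dH``,
the cumulative heat released is

    Q_i = (n M_i dH V0 / 2) [ r_i - sqrt(r_i^2 - 4 X_i / (n M_i)) ],
    r_i = 1 + X_i/(n M_i) + 1/(n K_a M_i)

and the per-injection heat applies the perfusion-cell displacement
correction  dQ_i = Q_i - Q_{i-1} + (dV_i/V0) (Q_i + Q_{i-1}) / 2.

Dilution follows the instrument-software convention for an overfilled cell:
with v the cumulative injected volume,

    M_i = M0 (1 - v/(2 V0)) / (1 + v/(2 V0)),
    X_i = X0 (v/V0) (1 - v/(2 V0)).

Fitting is nonlinear least squares on the normalized heats over
(n, log10 K_a, dH), with the customary exclusion of the small first
injection.  Derived quantities use dG = -R T ln K_a and T dS = dH - dG with
R = 1.9872 cal mol^-1 K^-1.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "R_CAL",
    "ThermoParams",
    "TitrationSchedule",
    "InjectionHeats",
    "FitFailureError",
    "simulate_titration",
    "fit_one_set_of_sites",
    "thermodynamic_linkage",
    "write_titration",
    "read_titration",
]

R_CAL = 1.9872  # cal mol^-1 K^-1
DEFAULT_T = 298.15  # K (25 C)


class FitFailureError(RuntimeError):
    """The least-squares fit failed to converge after bounded restarts."""


@dataclasses.dataclass
class ThermoParams:
    """Binding thermodynamics: n, K_a and dH, with derived dG, TdS, K_d.

    The derived fields are filled on construction from (n, K_a, dH, T) and
    validated: K_d = 1/K_a, dG = -R T ln K_a, TdS = dH - dG.
    """

    n: float
    K_a: float  # M^-1
    dH: float  # cal/mol
    T: float = DEFAULT_T  # K
    K_d: Optional[float] = None  # M
    dG: Optional[float] = None  # cal/mol
    TdS: Optional[float] = None  # cal/mol
    uncertainties: Optional[dict] = None  # asymptotic standard errors

    def __post_init__(self) -> None:
        if self.K_a <= 0 or self.T <= 0:
            raise ValueError("K_a and T must be positive")
        kd = 1.0 / self.K_a
        dg = -R_CAL * self.T * np.log(self.K_a)
        tds = self.dH - dg
        for name, given, derived in (
            ("K_d", self.K_d, kd),
            ("dG", self.dG, dg),
            ("TdS", self.TdS, tds),
        ):
            if given is not None and not np.isclose(given, derived, rtol=1e-6, atol=1e-12):
                raise ValueError(f"{name}={given} inconsistent with derived {derived}")
        self.K_d, self.dG, self.TdS = kd, dg, tds


@dataclasses.dataclass
class TitrationSchedule:
    """Cell/syringe concentrations and injection series of one experiment."""

    cell_volume: float  # mL
    cell_conc: float  # M, species in the cell
    syringe_conc: float  # M, injectant
    injection_volumes: list[float]  # uL, in injection order
    temperature: float = DEFAULT_T  # K

    def __post_init__(self) -> None:
        if min(self.cell_volume, self.cell_conc, self.syringe_conc) <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not self.injection_volumes or min(self.injection_volumes) <= 0:
            raise ValueError("injection volumes must be positive")

    @classmethod
    def vp_itc_default(cls) -> "TitrationSchedule":
        """2 mL cell of 10 uM titrated from a 100 uM syringe: one 5 uL
        injection then 19 x 15 uL, at 25 C."""
        return cls(
            cell_volume=2.0,
            cell_conc=10e-6,
            syringe_conc=100e-6,
            injection_volumes=[5.0] + [15.0] * 19,
            temperature=DEFAULT_T,
        )

    @classmethod
    def itc200_default(cls) -> "TitrationSchedule":
        """300 uL cell of 46 uM titrated with 19 x 2 uL of 460 uM, at 25 C."""
        return cls(
            cell_volume=0.3,
            cell_conc=46e-6,
            syringe_conc=460e-6,
            injection_volumes=[2.0] * 19,
            temperature=DEFAULT_T,
        )

    def cell_volume_l(self) -> float:
        return self.cell_volume * 1e-3

    def cumulative_volumes_l(self) -> np.ndarray:
        return np.cumsum(np.asarray(self.injection_volumes, dtype=float)) * 1e-6

    def concentrations(self) -> tuple[np.ndarray, np.ndarray]:
        """Dilution-corrected (M_i, X_i) in-cell totals after each injection."""
        v0 = self.cell_volume_l()
        v = self.cumulative_volumes_l()
        m = self.cell_conc * (1 - v / (2 * v0)) / (1 + v / (2 * v0))
        x = self.syringe_conc * (v / v0) * (1 - v / (2 * v0))
        return m, x


@dataclasses.dataclass
class InjectionHeats:
    """Per-injection heats: raw (ucal), normalized (cal/mol injectant), ratio."""

    raw: np.ndarray  # ucal
    normalized: np.ndarray  # cal per mol of injectant
    molar_ratio: np.ndarray  # injectant : cell species, after each injection

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        if not (len(self.raw) == len(self.normalized) == len(self.molar_ratio)):
            raise ValueError("raw, normalized, molar_ratio must have equal lengths")
        if np.any(np.diff(self.molar_ratio) <= 0):
            raise ValueError("molar_ratio must be strictly increasing")


def _cumulative_heat(
    n: float, ka: float, dh: float, m: np.ndarray, x: np.ndarray, v0: float
) -> np.ndarray:
    """Wiseman cumulative heat Q_i (cal) from in-cell totals."""
    r = 1.0 + x / (n * m) + 1.0 / (n * ka * m)
    disc = r * r - 4.0 * x / (n * m)
    if np.any(disc < -1e-12):
        raise ArithmeticError("negative discriminant in the binding isotherm")
    return (n * m * dh * v0 / 2.0) * (r - np.sqrt(np.maximum(disc, 0.0)))


def _model_heats(
    n: float, ka: float, dh: float, schedule: TitrationSchedule
) -> tuple[np.ndarray, np.ndarray]:
    """(per-injection heats dQ in cal, normalized heats in cal/mol)."""
    v0 = schedule.cell_volume_l()
    m, x = schedule.concentrations()
    q = _cumulative_heat(n, ka, dh, m, x, v0)
    dv = np.asarray(schedule.injection_volumes, dtype=float) * 1e-6
    q_prev = np.concatenate([[0.0], q[:-1]])
    dq = q - q_prev + (dv / v0) * (q + q_prev) / 2.0
    moles_injected = schedule.syringe_conc * dv
    return dq, dq / moles_injected


def simulate_titration(
    params: ThermoParams,
    schedule: TitrationSchedule,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> InjectionHeats:
    """Simulate the per-injection heats of a one-site titration.

    ``noise_sd`` is the standard deviation (cal/mol) of Gaussian noise added
    to the normalized heats; raw heats are kept consistent with the noisy
    normalized values.  Exothermic binding (dH < 0) gives negative heats.
    """
    dq, normalized = _model_heats(params.n, params.K_a, params.dH, schedule)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        normalized = normalized + rng.normal(0.0, noise_sd, size=normalized.shape)
    dv = np.asarray(schedule.injection_volumes, dtype=float) * 1e-6
    raw = normalized * schedule.syringe_conc * dv * 1e6  # ucal
    m, x = schedule.concentrations()
    return InjectionHeats(raw=raw, normalized=normalized, molar_ratio=x / m)


def fit_one_set_of_sites(
    heats: InjectionHeats,
    schedule: TitrationSchedule,
    exclude_first: bool = True,
) -> ThermoParams:
    """Fit (n, K_a, dH) to normalized heats by nonlinear least squares.

    The first injection is excluded by default (conventional for the small
    pre-injection).  K_a is fitted on a log scale; several K_a starting
    values are tried and the lowest-cost solution kept.  Asymptotic standard
    errors (from the Jacobian at the solution) are attached as
    ``uncertainties`` with keys "n", "K_a", "dH".
    """
    observed = np.asarray(heats.normalized, dtype=float)
    usable = np.ones(len(observed), dtype=bool)
    if exclude_first:
        usable[0] = False
    if usable.sum() < 5:
        raise FitFailureError(f"only {int(usable.sum())} usable injections; need >= 5")
    y = observed[usable]

    def residuals(theta: np.ndarray) -> np.ndarray:
        n, log10_ka, dh = theta
        _, model = _model_heats(n, 10.0 ** log10_ka, dh, schedule)
        return model[usable] - y

    dh0 = y[0] if abs(y[0]) > 1e-12 else -1.0
    ka_starts = [1.0 / schedule.cell_conc, 1e4, 1e6, 1e8, 1e10]
    best = None
    for ka0 in ka_starts:
        x0 = np.array([1.0, np.log10(ka0), dh0])
        try:
            sol = least_squares(
                residuals,
                x0,
                bounds=([1e-3, 0.0, -np.inf], [1e3, 15.0, np.inf]),
                x_scale=[1.0, 1.0, max(abs(dh0), 1.0)],
            )
        except (ValueError, ArithmeticError):
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitFailureError("one-set-of-sites fit did not converge from any start")

    n_fit, log10_ka, dh_fit = best.x
    ka_fit = 10.0 ** log10_ka

    # asymptotic standard errors via the Jacobian at the solution
    dof = max(len(y) - 3, 1)
    s2 = 2.0 * best.cost / dof
    unc = {}
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        unc = {
            "n": float(se[0]),
            "K_a": float(se[1] * ka_fit * np.log(10.0)),  # delta method
            "dH": float(se[2]),
        }
    except np.linalg.LinAlgError:
        unc = {"n": np.inf, "K_a": np.inf, "dH": np.inf}

    return ThermoParams(
        n=float(n_fit),
        K_a=float(ka_fit),
        dH=float(dh_fit),
        T=schedule.temperature,
        uncertainties=unc,
    )


def thermodynamic_linkage(dH: float, K_a: float, T: float = DEFAULT_T) -> ThermoParams:
    """Fill dG = -R T ln K_a, TdS = dH - dG and K_d = 1/K_a for given inputs."""
    return ThermoParams(n=1.0, K_a=K_a, dH=dH, T=T)


# ---------------------------------------------------------------------------
# Plain-text I/O: two-column TSV of (injection volume uL, raw heat ucal) plus
# a YAML schedule block.


def write_titration(
    heats: InjectionHeats,
    schedule: TitrationSchedule,
    tsv_path: str | Path,
    schedule_path: str | Path,
) -> None:
    import yaml

    lines = ["injection_volume_uL\theat_ucal"]
    for dv, q in zip(schedule.injection_volumes, heats.raw):
        lines.append(f"{dv:.6g}\t{q:.10g}")
    Path(tsv_path).write_text("\n".join(lines) + "\n")
    Path(schedule_path).write_text(
        yaml.safe_dump(
            {
                "cell_volume_mL": schedule.cell_volume,
                "cell_conc_M": schedule.cell_conc,
                "syringe_conc_M": schedule.syringe_conc,
                "injection_volumes_uL": list(map(float, schedule.injection_volumes)),
                "temperature_K": schedule.temperature,
            },
            sort_keys=False,
        )
    )


def read_titration(
    tsv_path: str | Path, schedule_path: str | Path
) -> tuple[InjectionHeats, TitrationSchedule]:
    import yaml

    cfg = yaml.safe_load(Path(schedule_path).read_text())
    schedule = TitrationSchedule(
        cell_volume=cfg["cell_volume_mL"],
        cell_conc=cfg["cell_conc_M"],
        syringe_conc=cfg["syringe_conc_M"],
        injection_volumes=list(cfg["injection_volumes_uL"]),
        temperature=cfg.get("temperature_K", DEFAULT_T),
    )
    rows = [
        line.split("\t")
        for line in Path(tsv_path).read_text().strip().splitlines()[1:]
    ]
    raw = np.array([float(r[1]) for r in rows])
    dv = np.array([float(r[0]) for r in rows]) * 1e-6
    if len(raw) != len(schedule.injection_volumes):
        raise ValueError("TSV row count does not match schedule length")
    normalized = raw * 1e-6 / (schedule.syringe_conc * dv)
    m, x = schedule.concentrations()
    return InjectionHeats(raw=raw, normalized=normalized, molar_ratio=x / m), schedule
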