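"""Reduced mass-action model of mitochondrial energetics.

An 11-reaction ODE scheme preserving the three-subsystem structure of
mitochondrial function — tricarboxylic acid cycle (TCA), electron transport
chain (ETC) and reactive-oxygen-species scavenging (ROS) — with the membrane
potential (delta-psi, mV) as an explicit state:

    R0  substrate supply              -> S            v = k0 (1 - [S]/S_max)
    R1  TCA oxidation      S + NAD    -> NADH         v = k1 [S][NAD]
    R2  complex I          NADH + Q   -> NAD + QH2    v = k2 [NADH][Q] e^(-psi/psi0)
    R3  complex III        QH2 + 2cox -> Q + 2cred    v = k3 [QH2][cox] e^(-psi/psi0)
    R4  complex IV         cred       -> cox          v = k4 [cred] e^(-psi/psi0)
    R5  ATP synthase       ADP        -> ATP          v = k5 [ADP] psi/(psi + Kpsi)
    R6  proton leak                                   v = k6 psi
    R7  ROS production     QH2        -> Q + O2-      v = k7 [QH2] e^(psi/psi1)
    R8  dismutation        O2-        -> H2O2         v = k8 [O2-]
    R9  peroxide clearance H2O2       ->              v = k9 [H2O2]
    R10 ATP consumption    ATP        -> ADP          v = k10 [ATP]

    d psi/dt = (a2 v2 + a3 v3 + a4 v4 - a5 v5 - v6) / C_mem

The exponential thermodynamic damping of the proton-pumping reactions and
the saturable synthase flux keep the reduced scheme bounded and give a
stable positive steady state with ATP/A_tot ~ 0.8 at the default constants.
Four moiety totals (NAD(H), Q(H2), cytochrome c, adenine nucleotides) are
conserved exactly by construction.

Drug action enters by scaling reaction rate constants with measured protein
fold changes (geometric mean over the proteins mapped to a reaction).
Readouts: steady-state ATP and membrane potential, subsystem fluxes, a 1%
local sensitivity per reaction, and a leave-one-reaction-at-reference
macroscopic sensitivity against a drug's full fold-change configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

logger = logging.getLogger(__name__)

SPECIES = ("S", "NADH", "NAD", "QH2", "Q", "c_red", "c_ox", "O2m", "H2O2", "ATP", "ADP")
PSI_INDEX = len(SPECIES)  # membrane potential is the last state
REACTIONS = tuple(f"R{i}" for i in range(11))

SUBSYSTEMS: dict[str, tuple[str, ...]] = {
    "TCA": ("R0", "R1"),
    "ETC": ("R2", "R3", "R4", "R5", "R6", "R10"),
    "ROS": ("R7", "R8", "R9"),
}

#: default many-to-one protein -> reaction mapping (ETC complex subunits,
#: TCA enzymes, SOD2 for dismutation), extensible by the caller
DEFAULT_PROTEIN_MAP: dict[str, str] = {
    "CS": "R1", "MDH2": "R1", "SUCLA2": "R1", "SUCLG1": "R1", "SUCLG2": "R1",
    "NDUFV1": "R2", "NDUFV2": "R2",
    "UQCRC1": "R3", "UQCRC2": "R3", "UQCRFS1": "R3",
    "COX4I1": "R4",
    "ATP5F1A": "R5", "ATP5F1B": "R5",
    "SOD2": "R8",
}

MAX_STEPS = 50_000
DT_SECONDS = 60.0
RATE_TOL = 1e-9  # relative time-derivative threshold declaring steady state


@dataclass
class MitoModel:
    """State, rate constants and conserved totals of the reduced scheme."""

    k: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATE_CONSTANTS))
    state: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_INITIAL_STATE))
    psi: float = 150.0  # mV
    psi0: float = 400.0  # mV, damping scale of proton-pumping reactions
    psi1: float = 400.0  # mV, ROS production boost scale
    k_psi: float = 200.0  # mV, synthase half-saturation
    s_max: float = 0.1  # mM, substrate level at which supply shuts off
    c_mem: float = 10.0  # effective capacitance (mM mV^-1 units of flux)
    #: proton-stoichiometry weights of the charging/discharging fluxes
    a: dict[str, float] = field(
        default_factory=lambda: {"R2": 4.0, "R3": 4.0, "R4": 2.0, "R5": 3.0}
    )

    @property
    def totals(self) -> dict[str, float]:
        s = self.state
        return {
            "N_tot": s["NADH"] + s["NAD"],
            "Q_tot": s["QH2"] + s["Q"],
            "C_tot": s["c_red"] + s["c_ox"],
            "A_tot": s["ATP"] + s["ADP"],
        }

    def vector(self) -> np.ndarray:
        return np.array([self.state[sp] for sp in SPECIES] + [self.psi])

    def with_vector(self, y: np.ndarray) -> "MitoModel":
        state = {sp: float(y[i]) for i, sp in enumerate(SPECIES)}
        return replace(self, state=state, psi=float(y[PSI_INDEX]))


DEFAULT_RATE_CONSTANTS: dict[str, float] = {
    "R0": 0.045,  # mM/s maximal substrate supply
    "R1": 0.4,    # /mM/s
    "R2": 1.0,    # /mM/s (before psi damping)
    "R3": 1.0,    # /mM/s
    "R4": 1.0,    # /s
    "R5": 0.2,    # /s (before psi saturation)
    "R6": 0.001,  # mM/s per mV leak; sets baseline psi near 165 mV
    "R7": 0.002,  # /s ROS side flux
    "R8": 1.0,    # /s dismutation
    "R9": 1.0,    # /s clearance
    "R10": 0.03,  # /s ATP consumption
}

DEFAULT_INITIAL_STATE: dict[str, float] = {
    "S": 0.5,
    "NADH": 0.5, "NAD": 0.5,
    "QH2": 0.5, "Q": 0.5,
    "c_red": 0.5, "c_ox": 0.5,
    "O2m": 0.001, "H2O2": 0.001,
    "ATP": 0.5, "ADP": 0.5,
}


def reaction_rates(model: MitoModel, y: np.ndarray) -> dict[str, float]:
    s = {sp: y[i] for i, sp in enumerate(SPECIES)}
    psi = y[PSI_INDEX]
    k = model.k
    damp = np.exp(-psi / model.psi0)
    boost = np.exp(psi / model.psi1)
    return {
        "R0": k["R0"] * max(1.0 - s["S"] / model.s_max, 0.0),
        "R1": k["R1"] * s["S"] * s["NAD"],
        "R2": k["R2"] * s["NADH"] * s["Q"] * damp,
        "R3": k["R3"] * s["QH2"] * s["c_ox"] * damp,
        "R4": k["R4"] * s["c_red"] * damp,
        "R5": k["R5"] * s["ADP"] * psi / (psi + model.k_psi),
        "R6": k["R6"] * psi,
        "R7": k["R7"] * s["QH2"] * boost,
        "R8": k["R8"] * s["O2m"],
        "R9": k["R9"] * s["H2O2"],
        "R10": k["R10"] * s["ATP"],
    }


def _rhs(t: float, y: np.ndarray, model: MitoModel) -> np.ndarray:
    v = reaction_rates(model, y)
    a = model.a
    d = {
        "S": v["R0"] - v["R1"],
        "NADH": v["R1"] - v["R2"],
        "NAD": v["R2"] - v["R1"],
        "QH2": v["R2"] - v["R3"] - v["R7"],
        "Q": v["R3"] + v["R7"] - v["R2"],
        "c_red": 2 * v["R3"] - v["R4"],
        "c_ox": v["R4"] - 2 * v["R3"],
        "O2m": v["R7"] - v["R8"],
        "H2O2": v["R8"] - v["R9"],
        "ATP": v["R5"] - v["R10"],
        "ADP": v["R10"] - v["R5"],
    }
    dpsi = (
        a["R2"] * v["R2"] + a["R3"] * v["R3"] + a["R4"] * v["R4"]
        - a["R5"] * v["R5"] - v["R6"]
    ) / model.c_mem
    return np.array([d[sp] for sp in SPECIES] + [dpsi])


# ---------------------------------------------------------------------------
# rate scaling by protein fold changes
# ---------------------------------------------------------------------------

def scale_rates(
    base: MitoModel,
    fold_changes: dict[str, float],
    mapping: dict[str, str] | None = None,
    aggregate: str = "geometric",
) -> MitoModel:
    """Multiply each reaction's rate constant by the aggregated fold change
    of the proteins mapped to it (geometric mean by default; arithmetic via
    ``aggregate="arithmetic"``). Unmapped reactions are unchanged."""
    mapping = DEFAULT_PROTEIN_MAP if mapping is None else mapping
    if any(fc <= 0 for fc in fold_changes.values()):
        raise ValueError("fold changes must be > 0")
    unknown = {r for r in mapping.values() if r not in REACTIONS}
    if unknown:
        raise ValueError(f"mapping targets unknown reactions: {sorted(unknown)}")
    per_reaction: dict[str, list[float]] = {}
    for protein, fc in fold_changes.items():
        r = mapping.get(protein, protein if protein in REACTIONS else None)
        if r is not None:
            per_reaction.setdefault(r, []).append(float(fc))
    k = dict(base.k)
    for r, fcs in per_reaction.items():
        if aggregate == "geometric":
            factor = float(np.exp(np.mean(np.log(fcs))))
        elif aggregate == "arithmetic":
            factor = float(np.mean(fcs))
        else:
            raise ValueError("aggregate must be 'geometric' or 'arithmetic'")
        k[r] = k[r] * factor
    return replace(base, k=k, state=dict(base.state))


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

@dataclass
class SteadyState:
    model: MitoModel
    converged: bool
    n_steps_equivalent: int
    readouts: dict[str, float]
    subsystem_fluxes: dict[str, float]

    @property
    def atp(self) -> float:
        return self.readouts["ATP"]

    @property
    def psi(self) -> float:
        return self.readouts["psi"]


def run_to_steady_state(
    model: MitoModel,
    max_steps: int = MAX_STEPS,
    dt: float = DT_SECONDS,
    tol: float = RATE_TOL,
) -> SteadyState:
    """Integrate (stiff BDF, adaptive internally) until every state's
    relative rate |dy/dt|/max(|y|, eps) falls below ``tol`` or the
    ``max_steps * dt`` horizon is exhausted."""
    y = model.vector()
    if np.any(y[:PSI_INDEX] < 0) or y[PSI_INDEX] <= 0:
        raise ValueError("initial state must be positive")
    t_end = max_steps * dt
    chunk = max(200 * dt, t_end / 250)
    t = 0.0
    converged = False
    while t < t_end:
        t_next = min(t + chunk, t_end)
        sol = solve_ivp(
            _rhs, (t, t_next), y, args=(model,), method="BDF",
            rtol=1e-9, atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed at t={t:.0f}s: {sol.message}")
        y = sol.y[:, -1]
        neg = y[:PSI_INDEX] < -1e-9
        if np.any(neg):
            raise RuntimeError(
                f"divergence: negative concentration of {SPECIES[int(np.argmax(neg))]}"
            )
        y[:PSI_INDEX] = np.clip(y[:PSI_INDEX], 0.0, None)
        if not np.all(np.isfinite(y)):
            raise RuntimeError("divergence: non-finite state")
        t = t_next
        rel = np.abs(_rhs(t, y, model)) / np.maximum(np.abs(y), 1e-12)
        if np.all(rel < tol):
            converged = True
            break

    final = model.with_vector(y)
    v = reaction_rates(final, y)
    fluxes = {
        name: float(np.mean([v[r] for r in members]))
        for name, members in SUBSYSTEMS.items()
    }
    readouts = {"ATP": final.state["ATP"], "psi": final.psi}
    return SteadyState(
        model=final,
        converged=converged,
        n_steps_equivalent=int(t / dt),
        readouts=readouts,
        subsystem_fluxes=fluxes,
    )


# ---------------------------------------------------------------------------
# exposure series and sensitivities
# ---------------------------------------------------------------------------

def simulate_exposure_series(
    base: MitoModel,
    trajectories: pd.DataFrame,
    mapping: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Steady-state ATP and membrane potential along a fold-change trajectory
    table (reactions/proteins x days), normalized to the day-0 values.

    The day-0 column must be all ones (reference condition). Non-converged
    time points are flagged and the series continues.
    """
    days = list(trajectories.columns)
    first = trajectories[days[0]]
    if not np.allclose(first.to_numpy(dtype=float), 1.0):
        raise ValueError("trajectory at t=0 must be all ones")
    rows = []
    ref_atp = ref_psi = None
    for day in days:
        fcs = trajectories[day].to_dict()
        ss = run_to_steady_state(scale_rates(base, fcs, mapping))
        if not ss.converged:
            logger.warning("no steady state at day %s; point flagged", day)
        if ref_atp is None:
            ref_atp, ref_psi = ss.atp, ss.psi
        rows.append(
            {
                "day": float(day),
                "atp_norm": ss.atp / ref_atp,
                "psi_norm": ss.psi / ref_psi,
                "converged": ss.converged,
            }
        )
    return pd.DataFrame(rows)


def sensitivity_local(
    model: MitoModel, perturbation: float = 0.01
) -> pd.Series:
    """Relative ATP change per fractional rate increase, per reaction.

    Each rate constant is raised by ``perturbation`` (1% by default) in turn
    and the system re-settled; sensitivity_r = (ATP' - ATP) / ATP / perturbation.
    """
    base_ss = run_to_steady_state(model)
    if not base_ss.converged:
        raise RuntimeError("baseline model did not reach steady state")
    # re-anchor the reference through the same warm-start protocol as the
    # perturbed runs, so zero-effect perturbations give exactly zero
    atp0 = run_to_steady_state(
        replace(model, state=dict(base_ss.model.state), psi=base_ss.model.psi)
    ).atp
    out = {}
    for r in REACTIONS:
        k = dict(model.k)
        k[r] = k[r] * (1.0 + perturbation)
        # warm start from the baseline steady state
        ss = run_to_steady_state(replace(model, k=k, state=dict(base_ss.model.state),
                                         psi=base_ss.model.psi))
        out[r] = (ss.atp - atp0) / atp0 / perturbation
    return pd.Series(out, name="atp_sensitivity")


def sensitivity_macro(
    base: MitoModel,
    drug_foldchanges: dict[str, float],
    mapping: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Leave-one-reaction-at-reference macroscopic sensitivity.

    For each reaction r: apply the drug's full fold-change configuration
    except r (kept at its reference rate), settle, and report
    effect_r = ATP(all-but-r) - ATP(all). Reactions are ranked by |effect|;
    the aggregated fold change applied to each reaction is reported alongside
    so functional importance can be contrasted with abundance change.
    """
    mapping = DEFAULT_PROTEIN_MAP if mapping is None else mapping
    full = scale_rates(base, drug_foldchanges, mapping)
    atp_all = run_to_steady_state(full).atp
    rows = []
    for r in REACTIONS:
        k = dict(full.k)
        k[r] = base.k[r]  # reference activity for this one reaction
        atp_but = run_to_steady_state(replace(full, k=k, state=dict(base.state))).atp
        rows.append(
            {
                "reaction": r,
                "fold_change": full.k[r] / base.k[r],
                "atp_effect": atp_but - atp_all,
            }
        )
    out = pd.DataFrame(rows).set_index("reaction")
    out["abs_effect"] = out["atp_effect"].abs()
    out["rank"] = out["abs_effect"].rank(ascending=False, method="min").astype(int)
    return out.drop(columns="abs_effect").sort_values("rank")
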