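"""Transfer of network predictions to a patient cohort.

Correlates the expression of candidate proteins in cardiac biopsies with the
left-ventricular ejection fraction (LVEF, in %) separately within a
chemotherapy-exposed ("cardiotoxic") group and a control cardiomyopathy group,
ranks proteins by the discordance of the two correlations, and measures how
much of a consensus response network is covered by the proteins detectable in
biopsies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CARDIOTOXIC = "cardiotoxic"
CONTROL = "control"


@dataclass
class PatientCohort:
    """Protein expression and clinical covariates for a biopsy cohort.

    Attributes
    ----------
    expression:
        Protein x patient matrix of normalized (log2) expression; NaN marks
        proteins not detected in a biopsy.
    lvef:
        Left-ventricular ejection fraction (%) per patient, in (0, 100].
    group:
        Per-patient group label, ``"cardiotoxic"`` or ``"control"``.
    therapy_days:
        Duration of anti-cancer therapy in days; NaN for control patients.
    signal_proteins:
        Proteins constructed (in synthetic cohorts) to carry an LVEF signal.
    """

    expression: pd.DataFrame
    lvef: pd.Series
    group: pd.Series
    therapy_days: pd.Series
    signal_proteins: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        patients = list(self.expression.columns)
        for name, s in (("lvef", self.lvef), ("group", self.group)):
            missing = set(patients) - set(s.index)
            if missing:
                raise ValueError(f"{name} missing for patients: {sorted(missing)}")
        bad = self.lvef[(self.lvef <= 0) | (self.lvef > 100)]
        if len(bad):
            raise ValueError(f"LVEF outside (0, 100] for {list(bad.index)}")
        bad_grp = set(self.group.unique()) - {CARDIOTOXIC, CONTROL}
        if bad_grp:
            raise ValueError(f"unknown group labels: {sorted(bad_grp)}")

    def patients_in(self, group: str) -> list[str]:
        return [p for p in self.expression.columns if self.group[p] == group]


def lvef_correlation(
    cohort: PatientCohort,
    group: str,
    min_pairs: int = 3,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-protein correlation of biopsy expression with LVEF within a group.

    Pairwise-complete: for each protein only patients with a non-missing
    expression value enter. Proteins with fewer than ``min_pairs`` complete
    pairs are reported with ``testable=False`` and NaN correlation.

    Returns a DataFrame indexed by protein with columns ``corr``, ``n_used``,
    ``testable``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unsupported correlation method: {method}")
    patients = cohort.patients_in(group)
    if not patients:
        raise ValueError(f"no patients in group {group!r}")
    lvef = cohort.lvef[patients].astype(float)
    expr = cohort.expression[patients]

    rows = []
    for protein, values in expr.iterrows():
        mask = values.notna().to_numpy()
        n = int(mask.sum())
        if n < min_pairs:
            rows.append((protein, np.nan, n, False))
            continue
        x = values.to_numpy(dtype=float)[mask]
        y = lvef.to_numpy()[mask]
        if method == "spearman":
            x = pd.Series(x).rank().to_numpy()
            y = pd.Series(y).rank().to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((protein, np.nan, n, False))
            continue
        c = float(np.corrcoef(x, y)[0, 1])
        rows.append((protein, c, n, True))
    return pd.DataFrame(
        rows, columns=["protein", "corr", "n_used", "testable"]
    ).set_index("protein")


def discordance(c_tox: pd.Series, c_ctrl: pd.Series) -> pd.DataFrame:
    """Rank proteins by the gap between group-wise LVEF correlations.

    ``discordance = c_tox - c_ctrl``; ``sign_flip`` flags proteins whose
    correlation changes sign between groups (c_tox * c_ctrl < 0). Sorted by
    |discordance| descending; ties broken by protein id for determinism.
    """
    shared = c_tox.index.intersection(c_ctrl.index)
    out = pd.DataFrame(
        {
            "c_tox": c_tox[shared].astype(float),
            "c_ctrl": c_ctrl[shared].astype(float),
        }
    )
    out["discordance"] = out["c_tox"] - out["c_ctrl"]
    out["sign_flip"] = (out["c_tox"] * out["c_ctrl"]) < 0
    out["_abs"] = out["discordance"].abs()
    # stable sort: |discordance| desc, protein id as deterministic tie-break
    out = (
        out.sort_index(kind="mergesort")
        .sort_values("_abs", ascending=False, kind="mergesort")
        .drop(columns="_abs")
    )
    return out


def network_coverage(consensus_nodes: set[str] | list[str], detected: set[str]) -> tuple[int, float]:
    """Count and fraction of consensus-network proteins found in a biopsy set."""
    nodes = set(consensus_nodes)
    if not nodes:
        raise ValueError("empty consensus network: coverage fraction undefined")
    covered = nodes & set(detected)
    return len(covered), len(covered) / len(nodes)


def fisher_z_interval(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation at sample size n."""
    from scipy import stats

    if n <= 3:
        return -1.0, 1.0
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))
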