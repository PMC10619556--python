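"""Reporter-gene (luciferase) assay normalization and agonist calls.

Raw luminescence is normalized to relative transcriptional activity (RTA),
anchored so that the vehicle control reads 0% and the positive control (100
nM T3) reads 100%:

    RTA = 100 x (test - VC_test) / (PC - VC_control)

where VC_test is the vehicle control of the test group's own arm. A compound
/arm is called agonist-positive when any dose reaches RTA >= 10% of the
positive control. RTA is invariant to affine rescaling of the luminometer
output (gain or offset changes cancel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RtaResult",
    "read_plate",
    "rta",
    "call_agonist",
    "compare_arms",
    "AssayError",
]

PLATE_COLUMNS = ["well_id", "role", "arm", "compound", "dose_molar", "luminescence", "replicate"]
ROLES = {"PC", "VC_control", "VC_test", "test"}
ARMS = ("parent", "inactive_s9", "phase1", "phase1_2")

#: PC/VC induction ratio below which a QC warning is attached (the assay is
#: expected to show several-fold induction of the positive control).
MIN_INDUCTION_FOLD = 4.8


class AssayError(ValueError):
    """Raised when a plate cannot be normalized (e.g. PC ~ VC)."""


@dataclass(frozen=True)
class RtaResult:
    compound: str
    arm: str
    dose: float
    rta_percent: float
    sd: float
    n: int
    qc_warning: str = ""


def read_plate(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: plate CSV missing columns {missing}")
    bad_roles = set(df["role"]) - ROLES
    if bad_roles:
        raise ValueError(f"{path}: unknown well roles {sorted(bad_roles)}")
    if (df["luminescence"] < 0).any():
        raise ValueError(f"{path}: negative luminescence values")
    return df


def _validate(plate: pd.DataFrame) -> None:
    if not (plate["role"] == "PC").any():
        raise AssayError("plate has no PC wells")
    if not (plate["role"] == "VC_control").any():
        raise AssayError("plate has no VC_control wells")


def rta(
    plate: pd.DataFrame,
    denominator_tol: float = 1e-9,
    use_sem: bool = False,
) -> list[RtaResult]:
    """Normalize a plate to percent-of-positive-control activity.

    Per compound/arm/dose, a replicate-level RTA is computed for each test
    well against its arm's vehicle-control mean, then summarized as mean and
    SD (or SEM with ``use_sem=True``) over replicates. Arms lacking their own
    vehicle wells fall back to the plate's VC_control.
    """
    _validate(plate)
    pc = plate.loc[plate["role"] == "PC", "luminescence"].mean()
    vc_control = plate.loc[plate["role"] == "VC_control", "luminescence"].mean()
    denom = pc - vc_control
    if abs(denom) <= denominator_tol * max(abs(pc), 1.0):
        raise AssayError("assay invalid: PC and VC_control means coincide")
    induction = pc / vc_control if vc_control > 0 else math.inf
    qc = "" if induction >= MIN_INDUCTION_FOLD else (
        f"PC/VC induction {induction:.2f}-fold below {MIN_INDUCTION_FOLD}"
    )

    results = []
    tests = plate[plate["role"] == "test"]
    for (compound, arm, dose), grp in tests.groupby(["compound", "arm", "dose_molar"], sort=True):
        arm_vc = plate[(plate["role"] == "VC_test") & (plate["arm"] == arm)]
        vc_test = arm_vc["luminescence"].mean() if len(arm_vc) else vc_control
        per_rep = 100.0 * (grp["luminescence"].to_numpy() - vc_test) / denom
        n = per_rep.size
        spread = float(np.std(per_rep, ddof=1)) if n > 1 else 0.0
        if use_sem and n > 1:
            spread /= math.sqrt(n)
        results.append(
            RtaResult(
                compound=str(compound),
                arm=str(arm),
                dose=float(dose),
                rta_percent=float(np.mean(per_rep)),
                sd=spread,
                n=int(n),
                qc_warning=qc,
            )
        )
    return results


def call_agonist(results: Sequence[RtaResult], threshold: float = 10.0) -> pd.DataFrame:
    """Per compound/arm agonist verdicts: positive iff any dose has RTA >=
    ``threshold`` percent of the positive control (boundary inclusive)."""
    if not results:
        raise ValueError("no RTA results to call")
    rows = []
    keyed: dict[tuple[str, str], list[RtaResult]] = {}
    for r in results:
        keyed.setdefault((r.compound, r.arm), []).append(r)
    for (compound, arm), rs in sorted(keyed.items()):
        best = max(rs, key=lambda r: r.rta_percent)
        rows.append(
            {
                "compound": compound,
                "arm": arm,
                "positive": bool(best.rta_percent >= threshold),
                "max_rta_percent": best.rta_percent,
                "max_rta_dose_molar": best.dose,
                "n_doses": len(rs),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["compound", "arm", "positive", "max_rta_percent", "max_rta_dose_molar", "n_doses"],
    )


def compare_arms(results: Sequence[RtaResult], arm_a: str, arm_b: str) -> pd.DataFrame:
    """Per compound/dose activity difference between two treatment arms.

    Delta = RTA(arm_b) - RTA(arm_a), with the SD pooled in quadrature.
    """
    a = {(r.compound, r.dose): r for r in results if r.arm == arm_a}
    b = {(r.compound, r.dose): r for r in results if r.arm == arm_b}
    if not a:
        raise ValueError(f"arm {arm_a!r} absent from results")
    if not b:
        raise ValueError(f"arm {arm_b!r} absent from results")
    rows = []
    for key in sorted(set(a) & set(b)):
        ra, rb = a[key], b[key]
        rows.append(
            {
                "compound": key[0],
                "dose_molar": key[1],
                f"rta_{arm_a}": ra.rta_percent,
                f"rta_{arm_b}": rb.rta_percent,
                "delta_rta": rb.rta_percent - ra.rta_percent,
                "pooled_sd": math.hypot(ra.sd, rb.sd),
            }
        )
    return pd.DataFrame(rows)


def results_frame(results: Sequence[RtaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound": r.compound,
                "arm": r.arm,
                "dose_molar": r.dose,
                "rta_percent": r.rta_percent,
                "sd": r.sd,
                "n": r.n,
                "qc_warning": r.qc_warning,
            }
            for r in results
        ]
    )
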