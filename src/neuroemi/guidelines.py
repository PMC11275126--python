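"""Executable checker for the six electrode-design rules.

Geometry rules (1–3) act on the probe layout; impedance rules (4–6) act on
the path-impedance plan:

1. every pairwise electrode distance > 20 µm (a closer pair sits inside one
   neuron and cancels its own spike);
2. every signal–reference distance within 20–200 µm (inside the local LFP
   spread, outside the single-neuron radius);
3. the ground electrode at the midpoint of each signal–reference pair (equal
   tissue impedances to ground keep the interference common-mode);
4. ground path impedance small (kiloohm range);
5. signal attenuation from electrode to amplifier below a bound;
6. reference path impedance matched to Z_S/N (rigorous) or everything far
   below the common-mode input impedance (extreme).

Thresholds are configurable and echoed verbatim in the report for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from . import constants as C
from .interference import MatchingScheme, check_extreme_matching
from .signal_path import RecordingSetup, attenuation_ratio
from .volume_conductor import ElectrodeSite

__all__ = ["GuidelineResult", "GuidelineReport", "check_geometry", "check_impedance_plan", "check_all"]

Status = Literal["pass", "warn", "fail"]


@dataclass(frozen=True)
class GuidelineResult:
    guideline: int
    status: Status
    measured: float
    threshold: float
    detail: str


@dataclass(frozen=True)
class GuidelineReport:
    """Per-guideline outcomes; each checked guideline appears exactly once."""

    results: tuple[GuidelineResult, ...]

    def __post_init__(self) -> None:
        ids = [r.guideline for r in self.results]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate guideline entries: {ids}")

    def __getitem__(self, guideline: int) -> GuidelineResult:
        for r in self.results:
            if r.guideline == guideline:
                return r
        raise KeyError(guideline)

    @property
    def passed(self) -> bool:
        return all(r.status != "fail" for r in self.results)

    def to_records(self) -> list[dict]:
        return [
            {
                "guideline": r.guideline,
                "status": r.status,
                "measured": r.measured,
                "threshold": r.threshold,
                "detail": r.detail,
            }
            for r in self.results
        ]


def _pairwise_min_distance(sites: Sequence[ElectrodeSite]) -> tuple[float, str]:
    best = (np.inf, "")
    for i, a in enumerate(sites):
        for b in sites[i + 1 :]:
            d = float(np.linalg.norm(np.subtract(a.position, b.position)))
            if d < best[0]:
                best = (d, f"{a.site_id}–{b.site_id}")
    return best


def check_geometry(
    sites: Sequence[ElectrodeSite],
    *,
    min_distance: float = C.MIN_INTER_ELECTRODE_DISTANCE_M,
    max_sig_ref_distance: float = C.MAX_SIGNAL_REFERENCE_DISTANCE_M,
    midpoint_tolerance: float = C.DEFAULT_MIDPOINT_TOLERANCE_FRACTION,
) -> GuidelineReport:
    """Geometry guidelines 1–3 for a probe layout.

    Distances are 3-D Euclidean; with multiple sites per role the worst pair
    drives each verdict.  Results are independent of site listing order.
    """
    by_role: dict[str, list[ElectrodeSite]] = {"signal": [], "reference": [], "ground": []}
    for s in sites:
        by_role[s.role].append(s)
    for role, members in by_role.items():
        if not members:
            raise ValueError(f"probe layout is missing a {role} electrode")

    # G1: minimum pairwise spacing over all electrodes
    d_min, pair = _pairwise_min_distance(list(sites))
    g1 = GuidelineResult(
        1,
        "pass" if d_min > min_distance else "fail",
        d_min,
        min_distance,
        f"closest pair {pair} at {d_min*1e6:.1f} µm (must exceed {min_distance*1e6:.0f} µm)",
    )

    # G2: every signal–reference distance inside [min_distance, max_sig_ref_distance]
    sr = [
        (float(np.linalg.norm(np.subtract(s.position, r.position))), f"{s.site_id}–{r.site_id}")
        for s in by_role["signal"]
        for r in by_role["reference"]
    ]
    worst = min(sr)[0], max(sr)[0]
    g2_ok = worst[0] >= min_distance and worst[1] <= max_sig_ref_distance
    g2_measured = worst[1] if worst[1] > max_sig_ref_distance else worst[0]
    g2 = GuidelineResult(
        2,
        "pass" if g2_ok else "fail",
        g2_measured,
        max_sig_ref_distance,
        f"signal–reference distances span {worst[0]*1e6:.1f}–{worst[1]*1e6:.1f} µm "
        f"(required {min_distance*1e6:.0f}–{max_sig_ref_distance*1e6:.0f} µm)",
    )

    # G3: ground at the midpoint of each signal–reference pair; worst pair reported
    worst_off = -np.inf
    worst_detail = ""
    worst_tol = 0.0
    for s in by_role["signal"]:
        for r in by_role["reference"]:
            mid = (np.asarray(s.position) + np.asarray(r.position)) / 2.0
            d_sr = float(np.linalg.norm(np.subtract(s.position, r.position)))
            # nearest ground site to this pair's midpoint
            dg = min(
                float(np.linalg.norm(np.asarray(g.position) - mid)) for g in by_role["ground"]
            )
            rel = dg / d_sr if d_sr > 0 else np.inf
            if rel > worst_off:
                worst_off, worst_tol = rel, midpoint_tolerance * d_sr
                worst_detail = (
                    f"ground is {dg*1e6:.1f} µm from the {s.site_id}–{r.site_id} midpoint "
                    f"(allowed {midpoint_tolerance*100:.0f}% of their {d_sr*1e6:.1f} µm span)"
                )
    g3 = GuidelineResult(
        3,
        "pass" if worst_off <= midpoint_tolerance else "fail",
        worst_off,
        midpoint_tolerance,
        worst_detail,
    )
    return GuidelineReport((g1, g2, g3))


def check_impedance_plan(
    setup: RecordingSetup,
    scheme: MatchingScheme,
    *,
    ground_bound: float = C.DEFAULT_GROUND_IMPEDANCE_BOUND_OHM,
    attenuation_bound_percent: float = C.DEFAULT_ATTENUATION_BOUND_PERCENT,
    extreme_factor: float = C.DEFAULT_EXTREME_MATCHING_FACTOR,
) -> GuidelineReport:
    """Impedance guidelines 4–6 for a recording setup under a matching scheme."""
    zg = abs(setup.Z_G.value)
    g4 = GuidelineResult(
        4,
        "pass" if zg <= ground_bound else "fail",
        zg,
        ground_bound,
        f"|Z_G| = {zg/1e3:.3g} kΩ (bound {ground_bound/1e3:.3g} kΩ)",
    )

    att = attenuation_ratio(setup)
    g5 = GuidelineResult(
        5,
        "pass" if att <= attenuation_bound_percent else "fail",
        att,
        attenuation_bound_percent,
        f"electrode→amplifier attenuation {att:.3g}% (bound {attenuation_bound_percent:.3g}%)",
    )

    if scheme.kind == "rigorous":
        target = setup.Z_S.value / scheme.N
        mismatch = abs(setup.Z_R.value - target) / abs(target)
        g6 = GuidelineResult(
            6,
            "pass" if mismatch <= scheme.tolerance else "fail",
            mismatch,
            scheme.tolerance,
            f"|Z_R − Z_S/N|/|Z_S/N| = {mismatch:.3g} for N={scheme.N} "
            f"(tolerance {scheme.tolerance:.3g})",
        )
    else:
        res = check_extreme_matching(setup, extreme_factor)
        g6 = GuidelineResult(
            6,
            "pass" if res.passed else "fail",
            1.0 / res.margin if res.margin > 0 else float("inf"),
            1.0,
            f"extreme matching margin {res.margin:.3g}× (residual CM→DM fraction "
            f"{res.residual_cmi_fraction:.3g})",
        )
    return GuidelineReport((g4, g5, g6))


def check_all(
    sites: Sequence[ElectrodeSite],
    setup: RecordingSetup,
    scheme: MatchingScheme,
    **kwargs,
) -> GuidelineReport:
    """All six guidelines in one report."""
    geo_kw = {k: kwargs[k] for k in ("min_distance", "max_sig_ref_distance", "midpoint_tolerance") if k in kwargs}
    imp_kw = {k: kwargs[k] for k in ("ground_bound", "attenuation_bound_percent", "extreme_factor") if k in kwargs}
    geo = check_geometry(sites, **geo_kw)
    imp = check_impedance_plan(setup, scheme, **imp_kw)
    return GuidelineReport(tuple(geo.results) + tuple(imp.results))
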