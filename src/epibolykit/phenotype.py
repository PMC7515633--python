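"""Phenotype scoring, penetrance and closed-form metabolic quantities.

Embryos are scored against stage-matched controls on an ordered
developmental stage scale: ``dead`` if coagulated, ``affected`` if
alive but arrested at an earlier epiboly stage than the control, and
``unaffected`` otherwise.  Penetrance is the percentage of affected
embryos over the tally denominator as printed in "n = x/y" style
reports (the denominator is explicit because published tallies do not
always equal unaffected + affected + dead).  The adenylate energy
charge (ATP + ADP/2) / (ATP + ADP + AMP) and the 2^-ddCt relative
expression fold change are provided as exact closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Default ordered epiboly/early-development stage scale (earliest first).
DEFAULT_STAGE_SCALE = (
    "sphere",
    "30%-epiboly",
    "50%-epiboly",
    "60%-epiboly",
    "75%-epiboly",
    "90%-epiboly",
    "bud",
    "3-somite",
)

CATEGORIES = ("unaffected", "affected", "dead")


@dataclass
class PhenotypeCounts:
    """Per-group tallies of scored embryos.

    ``denominator`` is the printed tally denominator (the y of
    "n = x/y"); it defaults to the category total when omitted.
    """

    group: str
    n_unaffected: int
    n_affected: int
    n_dead: int
    denominator: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_unaffected", "n_affected", "n_dead"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.denominator is None:
            self.denominator = self.n_unaffected + self.n_affected + self.n_dead
        if self.denominator <= 0:
            raise ValueError("denominator must be > 0")


@dataclass
class AdenylatePool:
    """ATP/ADP/AMP concentrations in one (arbitrary but common) unit."""

    atp: float
    adp: float
    amp: float

    def __post_init__(self) -> None:
        if min(self.atp, self.adp, self.amp) < 0:
            raise ValueError("concentrations must be >= 0")
        if self.atp + self.adp + self.amp == 0:
            raise ValueError("at least one concentration must be positive")


@dataclass
class CtMeasurements:
    """qPCR cycle thresholds for target/reference in treated/control."""

    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float

    def __post_init__(self) -> None:
        vals = (
            self.ct_target_treated,
            self.ct_ref_treated,
            self.ct_target_control,
            self.ct_ref_control,
        )
        if any(not math.isfinite(v) or v <= 0 for v in vals):
            raise ValueError("Ct values must be finite and positive")


def classify_embryo(
    embryo_stage: str,
    control_stage: str,
    alive: bool = True,
    stage_scale: tuple[str, ...] = DEFAULT_STAGE_SCALE,
) -> str:
    """Score one embryo against its stage-matched control.

    ``dead`` if not alive; ``affected`` if alive but at a strictly
    earlier stage than the control (developmental arrest/delay);
    ``unaffected`` otherwise.  Both stages must come from the declared
    ordinal scale.
    """
    if not alive:
        return "dead"
    for name, stage in (("embryo_stage", embryo_stage), ("control_stage", control_stage)):
        if stage not in stage_scale:
            raise ValueError(f"{name} {stage!r} not on the stage scale {stage_scale}")
    if stage_scale.index(embryo_stage) < stage_scale.index(control_stage):
        return "affected"
    return "unaffected"


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (matching hand-reported percentages)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def penetrance(counts: PhenotypeCounts) -> dict[str, float]:
    """Percent affected (and per-category percentages) for one group.

    ``affected_pct`` uses the printed tally denominator and one-decimal
    half-away-from-zero rounding, reproducing "n = x/y; p%" reports.
    Per-category percentages use the category total and sum to 100
    before rounding.
    """
    denom = counts.denominator
    assert denom is not None
    affected_pct = round_half_away(100.0 * counts.n_affected / denom)
    total = counts.n_unaffected + counts.n_affected + counts.n_dead
    if total == 0:
        raise ValueError("no scored embryos in group")
    return {
        "affected_pct": affected_pct,
        "unaffected_category_pct": 100.0 * counts.n_unaffected / total,
        "affected_category_pct": 100.0 * counts.n_affected / total,
        "dead_category_pct": 100.0 * counts.n_dead / total,
    }


def clutch_mean_penetrance(per_clutch: list[PhenotypeCounts]) -> tuple[float, float]:
    """Mean ± SEM of per-clutch affected percentages.

    Distinct from pooled penetrance: each clutch contributes one
    percentage regardless of its size.
    """
    if not per_clutch:
        raise ValueError("no clutches given")
    pcts = [100.0 * c.n_affected / c.denominator for c in per_clutch]  # type: ignore[operator]
    n = len(pcts)
    mean = sum(pcts) / n
    if n == 1:
        return mean, 0.0
    var = sum((p - mean) ** 2 for p in pcts) / (n - 1)
    return mean, math.sqrt(var / n)


def energy_charge(pool: AdenylatePool) -> float:
    """Adenylate energy charge: (ATP + ADP/2) / (ATP + ADP + AMP) in [0, 1]."""
    return (pool.atp + 0.5 * pool.adp) / (pool.atp + pool.adp + pool.amp)


def ddct_fold_change(ct: CtMeasurements) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,treated - Ct_ref,treated)
         - (Ct_target,control - Ct_ref,control); returns 2^-ddCt.
    """
    ddct = (ct.ct_target_treated - ct.ct_ref_treated) - (
        ct.ct_target_control - ct.ct_ref_control
    )
    return 2.0 ** (-ddct)
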