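"""Rule model of the PUCH endonuclease's substrate specificity.

The enzyme - a trimer requiring TOFU-1, TOFU-2 and either SLFL-3 or
SLFL-4 - cleaves a capped RNA between nucleotides 2 and 3 and leaves a
5'-monophosphate on the downstream product.  Cleavage demands an
m7G cap, a U at position 3, an intact catalytic glutamate (the E216A
variant is dead), no chelator, and a permissive divalent metal: Mg or Mn
at any tested concentration, Ca only at high concentration, never Zn.
A C at position 1 slows the reaction but does not abolish it; the
sequence beyond position 3 and the substrate's 3' length are irrelevant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Cap",
    "Metal",
    "Substrate",
    "EnzymeState",
    "ReactionConditions",
    "CleavageOutcome",
    "RuleConfig",
    "assess_substrate",
    "assess_mixture",
    "truth_table",
]

CLEAVAGE_SITE = 2  # scissile bond between positions 2 and 3 (1-based)

REQUIRED_SUBUNITS = frozenset({"TOFU-1", "TOFU-2"})
REDUNDANT_SUBUNITS = frozenset({"SLFL-3", "SLFL-4"})
ALL_SUBUNITS = REQUIRED_SUBUNITS | REDUNDANT_SUBUNITS


class Cap:
    M7G = "m7G"
    TMG = "TMG"
    MONOPHOSPHATE = "monophosphate_5p"
    HYDROXYL = "hydroxyl_5p"
    ALL = (M7G, TMG, MONOPHOSPHATE, HYDROXYL)


class Metal:
    MG = "Mg"
    MN = "Mn"
    CA = "Ca"
    ZN = "Zn"
    NONE = "none"
    ALL = (MG, MN, CA, ZN, NONE)


@dataclass(frozen=True)
class Substrate:
    cap: str
    sequence: str  # RNA alphabet; position 1 = 5'-most templated base
    label: str = ""

    def __post_init__(self) -> None:
        if self.cap not in Cap.ALL:
            raise ValueError(f"unknown cap chemistry {self.cap!r}")
        if len(self.sequence) < 3:
            raise ValueError("substrate needs at least 3 templated nucleotides")
        bad = set(self.sequence) - set("ACGU")
        if bad:
            raise ValueError(f"non-RNA characters in substrate: {sorted(bad)}")


@dataclass(frozen=True)
class EnzymeState:
    variant: str = "wild_type"  # "wild_type" | "E216A"
    subunits_present: frozenset[str] = field(default=frozenset(ALL_SUBUNITS))

    def __post_init__(self) -> None:
        if self.variant not in ("wild_type", "E216A"):
            raise ValueError(f"unknown variant {self.variant!r}")
        unknown = set(self.subunits_present) - ALL_SUBUNITS
        if unknown:
            raise ValueError(f"unknown subunits {sorted(unknown)}")

    @property
    def complex_assembles(self) -> bool:
        """Both TOFU subunits plus at least one of the redundant SLFL pair."""
        return REQUIRED_SUBUNITS <= self.subunits_present and bool(
            REDUNDANT_SUBUNITS & self.subunits_present
        )


@dataclass(frozen=True)
class ReactionConditions:
    metal: str = Metal.MG
    metal_concentration_mM: float = 11.0
    edta_present: bool = False

    def __post_init__(self) -> None:
        if self.metal not in Metal.ALL:
            raise ValueError(f"unknown metal {self.metal!r}")
        if self.metal_concentration_mM < 0:
            raise ValueError("metal concentration must be >= 0")


@dataclass(frozen=True)
class RuleConfig:
    """Quantitative knobs the qualitative observations leave open: the
    tested series was 1/4/11 mM, Ca supported cleavage only at the top of
    that range."""

    high_ca_threshold_mM: float = 11.0
    min_metal_mM: float = 1.0


@dataclass(frozen=True)
class CleavageOutcome:
    cleaved: bool
    site: int | None  # scissile bond index (after position `site`)
    product_5prime: str | None  # "monophosphate" when cleaved
    product_sequence: str | None
    rate_class: str  # "fast" | "slow" | "none"

    def __post_init__(self) -> None:
        if self.cleaved:
            if self.site != CLEAVAGE_SITE or self.product_5prime != "monophosphate":
                raise ValueError("cleaved outcomes must carry the canonical chemistry")
        elif self.rate_class != "none":
            raise ValueError("uncleaved outcomes have rate_class 'none'")


_NOT_CLEAVED = CleavageOutcome(False, None, None, None, "none")


def _metal_permissive(c: ReactionConditions, rules: RuleConfig) -> bool:
    if c.metal in (Metal.MG, Metal.MN):
        return c.metal_concentration_mM >= rules.min_metal_mM
    if c.metal == Metal.CA:
        return c.metal_concentration_mM >= rules.high_ca_threshold_mM
    return False


def assess_substrate(
    substrate: Substrate,
    enzyme: EnzymeState | None = None,
    conditions: ReactionConditions | None = None,
    rules: RuleConfig | None = None,
) -> CleavageOutcome:
    """Apply the full specificity rule set to one substrate."""
    enzyme = enzyme or EnzymeState()
    conditions = conditions or ReactionConditions()
    rules = rules or RuleConfig()
    seq = substrate.sequence
    competent = (
        enzyme.variant == "wild_type"
        and enzyme.complex_assembles
        and substrate.cap == Cap.M7G
        and seq[2] == "U"
        and not conditions.edta_present
        and _metal_permissive(conditions, rules)
    )
    if not competent:
        return _NOT_CLEAVED
    # position-1 C slows the reaction; A/G (and untested U) run at full speed
    rate = "slow" if seq[0] == "C" else "fast"
    return CleavageOutcome(
        cleaved=True,
        site=CLEAVAGE_SITE,
        product_5prime="monophosphate",
        product_sequence=seq[CLEAVAGE_SITE:],
        rate_class=rate,
    )


def assess_mixture(
    substrates: Sequence[Substrate] | Sequence[tuple[Substrate, int]],
    enzyme: EnzymeState | None = None,
    conditions: ReactionConditions | None = None,
    rules: RuleConfig | None = None,
) -> list[tuple[Substrate, CleavageOutcome]]:
    """Assess a substrate mixture; cleavage-incompetent substrates do not
    inhibit processing, so every outcome equals the solo outcome regardless
    of multiplicity or order."""
    out = []
    for item in substrates:
        substrate = item[0] if isinstance(item, tuple) else item
        out.append((substrate, assess_substrate(substrate, enzyme, conditions, rules)))
    return out


def truth_table(
    substrates: Iterable[Substrate],
    enzymes: Iterable[EnzymeState] | None = None,
    conditions: Iterable[ReactionConditions] | None = None,
    rules: RuleConfig | None = None,
) -> pd.DataFrame:
    """Cartesian evaluation over substrates x enzymes x conditions."""
    enzymes = list(enzymes) if enzymes is not None else [EnzymeState()]
    conditions = list(conditions) if conditions is not None else [ReactionConditions()]
    rows = []
    for s, e, c in itertools.product(substrates, enzymes, conditions):
        outcome = assess_substrate(s, e, c, rules)
        rows.append(
            {
                "label": s.label,
                "cap": s.cap,
                "seq_start": s.sequence[:3],
                "variant": e.variant,
                "subunits": "+".join(sorted(e.subunits_present)),
                "metal": c.metal,
                "metal_mM": c.metal_concentration_mM,
                "edta": c.edta_present,
                "cleaved": outcome.cleaved,
                "rate_class": outcome.rate_class,
                "product_length": (
                    len(outcome.product_sequence) if outcome.cleaved else None
                ),
            }
        )
    return pd.DataFrame(rows)
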