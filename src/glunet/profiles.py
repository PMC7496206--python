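"""Eight-type glucose-response profile taxonomy.

Each entity's pair of verdicts (low-vs-moderate, high-vs-moderate) maps to
one of eight discrete response shapes over the low -> moderate -> high
glucose series, plus FLAT for no change:

=====  ==========  ===========  =====================================
type   low vs mod  high vs mod  shape
=====  ==========  ===========  =====================================
I      down        up           increased continuously
D      up          down         decreased continuously
M      down        down         below moderate at both extremes
V      up          up           above moderate at both extremes
LD     down        nc           decreased under low glucose only
LI     up          nc           increased under low glucose only
HI     nc          up           increased under high glucose only
HD     nc          down         decreased under high glucose only
FLAT   nc          nc           no change
=====  ==========  ===========  =====================================

Under the assumption that miRNAs repress their targets, a miRNA and its
target show inverse profiles: I<->D, M<->V, LD<->LI, HI<->HD.
"""

from __future__ import annotations

import enum
import warnings
from collections import Counter
from typing import Iterable, Mapping

from glunet.diffexpr import DifferentialCall


class ProfileType(enum.Enum):
    I = "I"
    D = "D"
    M = "M"
    V = "V"
    LD = "LD"
    LI = "LI"
    HI = "HI"
    HD = "HD"
    FLAT = "FLAT"

    def __str__(self) -> str:  # compact in tables and logs
        return self.value


_GRID: dict[tuple[str, str], ProfileType] = {
    ("down", "up"): ProfileType.I,
    ("up", "down"): ProfileType.D,
    ("down", "down"): ProfileType.M,
    ("up", "up"): ProfileType.V,
    ("down", "nc"): ProfileType.LD,
    ("up", "nc"): ProfileType.LI,
    ("nc", "up"): ProfileType.HI,
    ("nc", "down"): ProfileType.HD,
    ("nc", "nc"): ProfileType.FLAT,
}

_INVERSE: dict[ProfileType, ProfileType] = {
    ProfileType.I: ProfileType.D,
    ProfileType.D: ProfileType.I,
    ProfileType.M: ProfileType.V,
    ProfileType.V: ProfileType.M,
    ProfileType.LD: ProfileType.LI,
    ProfileType.LI: ProfileType.LD,
    ProfileType.HI: ProfileType.HD,
    ProfileType.HD: ProfileType.HI,
}

#: per-condition verdict implied by each profile type
PROFILE_VERDICTS: dict[ProfileType, tuple[str, str]] = {
    t: calls for calls, t in _GRID.items()
}


def classify_profile(low_call: str, high_call: str) -> ProfileType:
    """Map a (low_vs_mod, high_vs_mod) verdict pair to its profile type.

    Both verdicts must be one of up / down / nc; filtered entities must
    be excluded (or mapped) by the caller.
    """
    key = (low_call, high_call)
    if key not in _GRID:
        raise ValueError(
            f"cannot classify verdict pair {key}; each verdict must be up/down/nc"
        )
    return _GRID[key]


def inverse_type(t: ProfileType) -> ProfileType:
    """The profile a repressed target shows when its miRNA shows ``t``."""
    if t is ProfileType.FLAT:
        raise ValueError("FLAT has no inverse profile")
    return _INVERSE[t]


def classify_entities(
    low_calls: Iterable[DifferentialCall],
    high_calls: Iterable[DifferentialCall],
) -> dict[str, ProfileType]:
    """Classify every entity from its two comparison calls.

    Entities filtered in *both* comparisons are dropped (never observed
    reliably); entities filtered in exactly one comparison are kept as
    FLAT with a warning, so downstream bookkeeping stays total while the
    inverse-pairing stage (which skips FLAT) excludes them.
    """
    low = {c.entity: c.verdict for c in low_calls}
    high = {c.entity: c.verdict for c in high_calls}
    if set(low) != set(high):
        raise ValueError("call lists cover different entity sets")
    out: dict[str, ProfileType] = {}
    half_filtered = 0
    for entity in low:
        lv, hv = low[entity], high[entity]
        if lv == "filtered" and hv == "filtered":
            continue
        if "filtered" in (lv, hv):
            half_filtered += 1
            out[entity] = ProfileType.FLAT
            continue
        out[entity] = classify_profile(lv, hv)
    if half_filtered:
        warnings.warn(
            f"{half_filtered} entities passed the abundance floor in only one "
            "comparison; assigned FLAT and excluded from pairing",
            stacklevel=2,
        )
    return out


def type_counts(assignments: Mapping[str, ProfileType]) -> dict[ProfileType, int]:
    """Number of entities per profile type (all nine classes reported)."""
    counts = Counter(assignments.values())
    return {t: counts.get(t, 0) for t in ProfileType}
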