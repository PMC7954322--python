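"""Health-state coding and classification from activity-limitation items.

The process has three states: two recurrent living states, ``HEALTHY`` (1)
and ``UNHEALTHY`` (2), between which individuals may move any number of
times, and an absorbing ``DEAD`` state (3).  The unhealthy state is derived
from self-reported limitations in basic activities of daily living (ADL:
bathing, walking across a room, getting in or out of bed, eating), with an
optional broader definition that also uses instrumental ADLs (IADL) and
mobility-function (MF) items.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

HEALTHY = 1
UNHEALTHY = 2
DEAD = 3

LIVING_STATES = (HEALTHY, UNHEALTHY)
ALL_STATES = (HEALTHY, UNHEALTHY, DEAD)

#: Allowed instantaneous transitions of the illness-death-with-recovery model.
TRANSITIONS = ((HEALTHY, UNHEALTHY), (HEALTHY, DEAD),
               (UNHEALTHY, HEALTHY), (UNHEALTHY, DEAD))

STATE_LABELS = {HEALTHY: "healthy", UNHEALTHY: "unhealthy", DEAD: "dead"}

#: Number of basic ADL items in the uniform four-item definition.
N_ADL_ITEMS = 4


def derive_health_state(
    adl_flags: Sequence[bool],
    iadl_flags: Optional[Iterable[bool]] = None,
    mf_flags: Optional[Iterable[bool]] = None,
    definition: str = "adl4",
) -> int:
    """Classify a living respondent as healthy (1) or unhealthy (2).

    Parameters
    ----------
    adl_flags
        Exactly four booleans, one per basic ADL item (limitation present).
    iadl_flags, mf_flags
        Instrumental-ADL and mobility-function limitation flags; required
        for the ``"sabe"`` definition, ignored by ``"adl4"``.
    definition
        ``"adl4"``: unhealthy iff at least one of the four ADL limitations.
        ``"sabe"``: unhealthy iff >=1 ADL, or >=2 IADL, or >=3 MF
        limitations (the broader functional-limitation definition used in
        the SABE study for Latin-American surveys).

    Never returns the dead state: vital status is recorded separately.
    """
    adl = [bool(f) for f in adl_flags]
    if len(adl) != N_ADL_ITEMS:
        raise ValueError(
            f"adl_flags must have exactly {N_ADL_ITEMS} entries, got {len(adl)}"
        )
    if definition == "adl4":
        return UNHEALTHY if any(adl) else HEALTHY
    if definition == "sabe":
        if iadl_flags is None or mf_flags is None:
            raise ValueError(
                "definition 'sabe' requires both iadl_flags and mf_flags"
            )
        iadl = [bool(f) for f in iadl_flags]
        mf = [bool(f) for f in mf_flags]
        unhealthy = any(adl) or sum(iadl) >= 2 or sum(mf) >= 3
        return UNHEALTHY if unhealthy else HEALTHY
    raise ValueError(f"unknown health-state definition: {definition!r}")
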