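"""Registry of the 20 probabilistic white-matter tracts used for regional volumetry.

The names follow the JHU white-matter tractography atlas: nine bilateral
tracts plus the two forceps. Curve-pattern groupings reflect the three
qualitative classes of regional WMH accumulation reported for these tracts:
pattern 1 tracts track total WMH volume from middle age onward, pattern 2
tracts stay near-empty until roughly age 60 and then accelerate, pattern 3
tracts rarely carry WMH at any age.
"""

from __future__ import annotations

_BILATERAL = (
    "anterior_thalamic_radiation",
    "corticospinal_tract",
    "cingulum_cingulate_gyrus",
    "cingulum_hippocampus",
    "inferior_fronto_occipital_fasciculus",
    "inferior_longitudinal_fasciculus",
    "superior_longitudinal_fasciculus",
    "superior_longitudinal_fasciculus_temporal",
    "uncinate_fasciculus",
)

#: Canonical ordering of the 20 tract names (registry order used for CSV columns).
JHU_TRACT_NAMES: tuple[str, ...] = ("forceps_major", "forceps_minor") + tuple(
    f"{base}_{side}" for base in _BILATERAL for side in ("l", "r")
)

#: Generative curve-pattern class per tract (1: total-like, 2: late-onset, 3: rare).
TRACT_PATTERNS: dict[str, int] = {}
for _name in JHU_TRACT_NAMES:
    if _name.startswith(("forceps", "anterior_thalamic", "inferior_fronto")):
        TRACT_PATTERNS[_name] = 1
    elif _name.startswith(
        ("superior_longitudinal_fasciculus_temporal", "cingulum")
    ):
        TRACT_PATTERNS[_name] = 3
    else:
        # SLF (non-temporal), ILF, corticospinal, uncinate
        TRACT_PATTERNS[_name] = 2


def validate_tract_names(names) -> list[str]:
    """Check a collection of tract names for duplicates; return them as a list.

    Unknown (non-JHU) names are allowed — the atlas is pluggable — but
    duplicates are always an error.
    """
    names = list(names)
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise ValueError(f"duplicate tract name: {n!r}")
        seen.add(n)
    return names
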