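"""Vertebral level naming and numeric indices.

Levels are numbered 1..24: 1-7 cervical (C1-C7), 8-19 thoracic (T1-T12),
20-24 lumbar (L1-L5).  An intervertebral disk is identified by the numeric
index of its upper vertebra: disk 2 is the C2-C3 disk, disk 8 the T1-T2
disk, and so on.
"""

from __future__ import annotations

N_CERVICAL = 7
N_THORACIC = 12
N_LUMBAR = 5
MAX_LEVEL = N_CERVICAL + N_THORACIC + N_LUMBAR  # 24 == L5


def level_name(index: int) -> str:
    """Return the anatomical name ('C4', 'T1', 'L5') of a numeric level."""
    index = int(index)
    if not 1 <= index <= MAX_LEVEL:
        raise ValueError(f"vertebral index out of range 1..{MAX_LEVEL}: {index}")
    if index <= N_CERVICAL:
        return f"C{index}"
    if index <= N_CERVICAL + N_THORACIC:
        return f"T{index - N_CERVICAL}"
    return f"L{index - N_CERVICAL - N_THORACIC}"


def level_index(level: int | str) -> int:
    """Parse a vertebral level given as an index or a name like 'C4'/'T12'."""
    if isinstance(level, str):
        name = level.strip().upper()
        if name and name[0] in "CTL":
            try:
                num = int(name[1:])
            except ValueError as exc:
                raise ValueError(f"cannot parse vertebral level {level!r}") from exc
            offset = {"C": 0, "T": N_CERVICAL, "L": N_CERVICAL + N_THORACIC}[name[0]]
            idx = offset + num
        else:
            idx = int(name)
    else:
        idx = int(level)
    if not 1 <= idx <= MAX_LEVEL:
        raise ValueError(f"vertebral index out of range 1..{MAX_LEVEL}: {level!r}")
    return idx


def disk_name(upper_level: int) -> str:
    """Name of the disk whose upper vertebra is ``upper_level``, e.g. 'C2-C3'."""
    return f"{level_name(upper_level)}-{level_name(upper_level + 1)}"
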