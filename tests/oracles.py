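"""Brute-force reference implementations used only to check the package.

These stay deliberately independent of the code paths they verify: the HSE
oracle enumerates every candidate window with regular expressions instead of
walking a phase lattice.
"""

from __future__ import annotations

import re
from functools import lru_cache


@lru_cache(maxsize=None)
def _pattern(n_units: int, first_core: str) -> re.Pattern:
    cores = []
    core = first_core
    for _ in range(n_units):
        cores.append(core)
        core = "TTC" if core == "GAA" else "GAA"
    return re.compile("".join(f"[ACGTN]{c}[ACGTN]" for c in cores))


def _qualifies(seq: str, pos: int, n_units: int, first_core: str) -> bool:
    if pos < 0 or pos + 5 * n_units > len(seq):
        return False
    return _pattern(n_units, first_core).fullmatch(seq, pos, pos + 5 * n_units) is not None


def brute_force_hse(seq: str, min_units: int = 3) -> list[tuple[int, int, str]]:
    """All maximal alternating nGAAn/nTTCn arrays as (start, n_units, type).

    A window qualifies when every pentamer carries the expected alternating
    exact core; a qualifying window is maximal when it cannot be extended by
    one unit on either side within its phase.
    """
    upper = seq.upper()
    found = []
    for pos in range(len(upper) - 4):
        core = upper[pos + 1 : pos + 4]
        if core not in ("GAA", "TTC"):
            continue
        n = min_units
        while _qualifies(upper, pos, n, core):
            prev_core = "TTC" if core == "GAA" else "GAA"
            left = _qualifies(upper, pos - 5, n + 1, prev_core)
            right = _qualifies(upper, pos, n + 1, core)
            if not left and not right:
                found.append((pos, n, "head" if core == "GAA" else "tail"))
            n += 1
    return sorted(set(found))
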