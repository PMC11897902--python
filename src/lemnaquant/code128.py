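"""Code128 barcode encoding and scanline decoding.

The tube labels carry Code128 symbols holding unique sample identifiers.
Encoding is needed by the synthetic fixture renderer; decoding backs the
threshold/rotation retry search in :mod:`lemnaquant.sideview`.

Both directions work on the module level: a Code128 symbol is 11 modules
wide, laid out as 3 bars and 3 spaces whose widths (1-4 modules) sum to 11;
the stop pattern is 13 modules (4 bars / 3 spaces).  The decoder measures
dark/light run lengths along horizontal scanlines of a binarized image,
quantizes each 6-run group to module widths and looks the widths up in the
symbology table, then validates the checksum.
"""

from __future__ import annotations

import numpy as np

# Bar/space module widths for symbol values 0-105, as 6-digit strings
# (bar, space, bar, space, bar, space).  Value 106 is the stop pattern.
_PATTERNS = [
    "212222", "222122", "222221", "121223", "121322", "131222", "122213",
    "122312", "132212", "221213", "221312", "231212", "112232", "122132",
    "122231", "113222", "123122", "123221", "223211", "221132", "221231",
    "213212", "223112", "312131", "311222", "321122", "321221", "312212",
    "322112", "322211", "212123", "212321", "232121", "111323", "131123",
    "131321", "112313", "132113", "132311", "211313", "231113", "231311",
    "112133", "112331", "132131", "113123", "113321", "133121", "313121",
    "211331", "231131", "213113", "213311", "213131", "311123", "311321",
    "331121", "312113", "312311", "332111", "314111", "221411", "431111",
    "111224", "111422", "121124", "121421", "141122", "141221", "112214",
    "112412", "122114", "122411", "142112", "142211", "241211", "221114",
    "413111", "241112", "134111", "111242", "121142", "121241", "114212",
    "124112", "124211", "411212", "421112", "421211", "212141", "214121",
    "412121", "111143", "111341", "131141", "114113", "114311", "411113",
    "411311", "113141", "114131", "311141", "411131", "211412", "211214",
    "211232",
]
_STOP = "2331112"  # 7 elements, 13 modules, ends on a bar

START_A, START_B, START_C = 103, 104, 105
_CODE_A, _CODE_B, _CODE_C = 101, 100, 99
_SHIFT = 98
_FNC_VALUES = {96, 97, 102}  # FNC1-4 share values with shifts depending on set

_PATTERN_TO_VALUE = {p: v for v, p in enumerate(_PATTERNS)}


def _char_to_value_b(ch: str) -> int:
    o = ord(ch)
    if not 32 <= o <= 126:
        raise ValueError(f"character {ch!r} not encodable in Code set B")
    return o - 32


def encode_values(payload: str) -> list[int]:
    """Symbol values (start..checksum, stop excluded) for *payload*.

    Pure even-length digit strings use Code set C (two digits per symbol);
    everything else uses Code set B.
    """
    if not payload:
        raise ValueError("empty payload")
    if payload.isdigit() and len(payload) % 2 == 0:
        values = [START_C] + [
            int(payload[i : i + 2]) for i in range(0, len(payload), 2)
        ]
    else:
        values = [START_B] + [_char_to_value_b(c) for c in payload]
    checksum = values[0]
    for i, v in enumerate(values[1:], start=1):
        checksum += i * v
    values.append(checksum % 103)
    return values


def encode_modules(payload: str, quiet_zone: int = 10) -> np.ndarray:
    """1-D module array for *payload*: 1 = bar (dark), 0 = space (light)."""
    bits: list[int] = [0] * quiet_zone
    for value in encode_values(payload):
        for i, w in enumerate(_PATTERNS[value]):
            bits.extend([1 - i % 2] * int(w))
    for i, w in enumerate(_STOP):
        bits.extend([1 - i % 2] * int(w))
    bits.extend([0] * quiet_zone)
    return np.asarray(bits, dtype=np.uint8)


def _runs_to_symbol(runs: np.ndarray, n_modules: int) -> str | None:
    """Quantize a group of runs to module widths; None if inconsistent."""
    total = runs.sum()
    if total <= 0:
        return None
    widths = np.rint(runs * (n_modules / total)).astype(int)
    if widths.sum() != n_modules or (widths < 1).any() or (widths > 4).any():
        return None
    return "".join(str(w) for w in widths)


def _values_to_text(values: list[int]) -> str | None:
    """Decode data symbol values (start included, checksum/stop excluded)."""
    start = values[0]
    if start not in (START_A, START_B, START_C):
        return None
    code = {START_A: "A", START_B: "B", START_C: "C"}[start]
    out: list[str] = []
    shift: str | None = None
    for v in values[1:]:
        active = shift or code
        shift = None
        if active == "C":
            if v < 100:
                out.append(f"{v:02d}")
            elif v == _CODE_B:
                code = "B"
            elif v == _CODE_A:
                code = "A"
            # FNC1 (102) skipped
        else:
            if active == "B" and v < 96:
                out.append(chr(v + 32))
            elif active == "A" and v < 96:
                out.append(chr(v + 32) if v < 64 else chr(v - 64))
            elif v == _CODE_C:
                code = "C"
            elif v == _CODE_B and active == "A":
                code = "B"
            elif v == _CODE_A and active == "B":
                code = "A"
            elif v == _SHIFT:
                shift = "A" if active == "B" else "B"
            # FNC symbols skipped
    return "".join(out)


def decode_scanline(dark: np.ndarray) -> str | None:
    """Decode one binarized scanline (boolean, True = dark); None on failure."""
    dark = np.asarray(dark, dtype=bool)
    if dark.size == 0 or not dark.any():
        return None
    # run-length encode; first/last runs are quiet-zone light runs to trim
    edges = np.flatnonzero(np.diff(dark.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [dark.size]))
    lengths = np.diff(bounds)
    first_dark = 0 if dark[0] else 1
    runs = lengths[first_dark:]  # starts on a bar
    # trim trailing light run (quiet zone); runs must end on the stop's bar
    if runs.size % 2 == 0:
        runs = runs[:-1]
    values: list[int] = []
    idx = 0
    while True:
        if idx + 7 <= runs.size:
            stop = _runs_to_symbol(runs[idx : idx + 7], 13)
            if stop == _STOP and len(values) >= 3:
                break
        if idx + 6 > runs.size:
            return None
        pattern = _runs_to_symbol(runs[idx : idx + 6], 11)
        if pattern is None or pattern not in _PATTERN_TO_VALUE:
            return None
        values.append(_PATTERN_TO_VALUE[pattern])
        if len(values) == 1 and values[0] not in (START_A, START_B, START_C):
            return None
        idx += 6
    checksum = values[0]
    for i, v in enumerate(values[1:-1], start=1):
        checksum += i * v
    if checksum % 103 != values[-1]:
        return None
    return _values_to_text(values[:-1])


def decode_image(dark: np.ndarray, n_scanlines: int = 7) -> str | None:
    """Try several horizontal scanlines of a binarized 2-D image.

    Parameters
    ----------
    dark
        2-D boolean array, True where the image is dark (bars).
    n_scanlines
        Number of evenly spaced rows (central band) to attempt.
    """
    dark = np.asarray(dark, dtype=bool)
    if dark.ndim != 2:
        raise ValueError("decode_image expects a 2-D array")
    h = dark.shape[0]
    rows = np.unique(np.linspace(0.2 * h, 0.8 * h, n_scanlines).astype(int))
    for r in rows:
        if 0 <= r < h:
            payload = decode_scanline(dark[r])
            if payload is not None:
                return payload
    return None
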