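"""Minimal Praat TextGrid text-format reader/writer.

Only what alignment I/O needs: interval tiers, long ("ooTextFile" with
``item []`` blocks) or short format, UTF-8/UTF-16 text.  Point tiers are
skipped.  This is deliberately small plumbing, not a general Praat library.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

Interval = tuple[float, float, str]  # (xmin, xmax, text)


def _read_text(path: str | Path) -> str:
    data = Path(path).read_bytes()
    if data[:2] in (b"\xfe\xff", b"\xff\xfe"):
        return data.decode("utf-16")
    return data.decode("utf-8")


def read_textgrid_tiers(path: str | Path) -> dict[str, list[Interval]]:
    """Return ``{tier_name: [(xmin, xmax, text), ...]}`` for interval tiers."""
    text = _read_text(path)
    if "ooTextFile" not in text.split("\n", 1)[0] and "ooTextFile" not in text:
        raise ValueError(f"{path}: not a Praat ooTextFile TextGrid")
    if re.search(r"item\s*\[", text):
        return _parse_long(text)
    return _parse_short(text)


_NUM = re.compile(r"^\s*\w[\w ]*=\s*([-\d.eE+]+)\s*$")
_STR = re.compile(r'^\s*\w[\w ]*=\s*"(.*)"\s*$', re.DOTALL)


def _parse_long(text: str) -> dict[str, list[Interval]]:
    tiers: dict[str, list[Interval]] = {}
    # split into item blocks (tier definitions)
    blocks = re.split(r"item\s*\[\d+\]\s*:", text)[1:]
    for block in blocks:
        cls = re.search(r'class\s*=\s*"([^"]*)"', block)
        name = re.search(r'name\s*=\s*"([^"]*)"', block)
        if cls is None or name is None:
            continue
        if cls.group(1) != "IntervalTier":
            continue
        intervals: list[Interval] = []
        for m in re.finditer(
            r"intervals\s*\[\d+\]\s*:\s*"
            r"xmin\s*=\s*([-\d.eE+]+)\s*"
            r"xmax\s*=\s*([-\d.eE+]+)\s*"
            r'text\s*=\s*"((?:[^"]|"")*)"',
            block,
        ):
            xmin, xmax = float(m.group(1)), float(m.group(2))
            label = m.group(3).replace('""', '"')
            intervals.append((xmin, xmax, label))
        tiers[name.group(1)] = intervals
    return tiers


def _parse_short(text: str) -> dict[str, list[Interval]]:
    # token stream: every non-empty line after the 2-line header + blank line
    lines = [ln.strip() for ln in text.splitlines()]
    toks = [ln for ln in lines[2:] if ln != ""]
    pos = 0

    def take() -> str:
        nonlocal pos
        tok = toks[pos]
        pos += 1
        return tok

    def take_str() -> str:
        tok = take()
        return tok[1:-1].replace('""', '"') if tok.startswith('"') else tok

    take()  # xmin
    take()  # xmax
    flag = take()  # <exists> / <absent>
    if "absent" in flag:
        return {}
    n_tiers = int(take())
    tiers: dict[str, list[Interval]] = {}
    for _ in range(n_tiers):
        cls = take_str()
        name = take_str()
        take()  # tier xmin
        take()  # tier xmax
        n = int(take())
        intervals: list[Interval] = []
        if cls == "IntervalTier":
            for _ in range(n):
                xmin = float(take())
                xmax = float(take())
                label = take_str()
                intervals.append((xmin, xmax, label))
            tiers[name] = intervals
        else:  # point tier: skip number + mark per point
            for _ in range(n):
                take()
                take_str()
    return tiers


def write_textgrid_file(
    path: str | Path, tiers: dict[str, Sequence[Interval]]
) -> None:
    """Write interval tiers as a long-format TextGrid, padding non-covered
    stretches with empty-label intervals so each tier is contiguous."""
    xmin = min((iv[0] for ivs in tiers.values() for iv in ivs), default=0.0)
    xmax = max((iv[1] for ivs in tiers.values() for iv in ivs), default=1.0)
    out = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {xmin:.6f}",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        f"size = {len(tiers)}",
        "item []:",
    ]
    for ti, (name, ivs) in enumerate(tiers.items(), start=1):
        padded: list[Interval] = []
        cursor = xmin
        for a, b, label in sorted(ivs):
            if a > cursor + 1e-9:
                padded.append((cursor, a, ""))
            padded.append((a, b, label))
            cursor = b
        if cursor < xmax - 1e-9:
            padded.append((cursor, xmax, ""))
        out += [
            f"    item [{ti}]:",
            '        class = "IntervalTier"',
            f'        name = "{name}"',
            f"        xmin = {xmin:.6f}",
            f"        xmax = {xmax:.6f}",
            f"        intervals: size = {len(padded)}",
        ]
        for ii, (a, b, label) in enumerate(padded, start=1):
            out += [
                f"        intervals [{ii}]:",
                f"            xmin = {a:.6f}",
                f"            xmax = {b:.6f}",
                f'            text = "{label.replace(chr(34), chr(34) * 2)}"',
            ]
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")
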