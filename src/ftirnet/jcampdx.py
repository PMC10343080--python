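"""Reading and writing FTIR spectra in JCAMP-DX 4.24 plain-text format.

Supports single-spectrum blocks whose data table is either an
``##XYPOINTS=(XY..XY)`` list of pairs or an AFFN-encoded
``##XYDATA=(X++(Y..Y))`` table.  Compressed ordinate forms
(SQZ/DIF/DUP pseudo-digits) are not supported and raise a parse error.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RawSpectrum",
    "JcampParseError",
    "JcampDataError",
    "read_jcampdx",
    "write_jcampdx",
]


class JcampParseError(ValueError):
    """Structural problem in a JCAMP-DX file (missing/garbled label)."""


class JcampDataError(ValueError):
    """A decoded data value is unusable (non-finite, inconsistent)."""


@dataclass
class RawSpectrum:
    """A parsed absorbance spectrum: wavenumber/absorbance pairs plus metadata.

    Wavenumbers are in cm^-1 and strictly ascending after canonicalization;
    absorbances are dimensionless absorbance units.
    """

    sample_id: str
    wavenumbers: np.ndarray
    absorbances: np.ndarray
    source_path: str | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.wavenumbers.ndim != 1 or self.absorbances.ndim != 1:
            raise JcampDataError("wavenumbers and absorbances must be 1-D")
        if len(self.wavenumbers) != len(self.absorbances):
            raise JcampDataError(
                f"length mismatch: {len(self.wavenumbers)} wavenumbers vs "
                f"{len(self.absorbances)} absorbances"
            )
        if len(self.wavenumbers) < 2:
            raise JcampDataError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(self.wavenumbers)) or not np.all(
            np.isfinite(self.absorbances)
        ):
            raise JcampDataError("non-finite value in spectrum")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise JcampDataError("wavenumbers must be strictly ascending")

    @property
    def n_points(self) -> int:
        return len(self.wavenumbers)


# JCAMP labelled-data-record: ##LABEL= content (content may continue on
# following lines until the next ## label).
_LDR_RE = re.compile(r"^\s*##([^=]*)=\s*(.*)$")

# AFFN numeric token, with optional leading sign; also matches exponent forms.
_NUM_RE = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")

# Pseudo-digits used by SQZ/DIF/DUP compression; their presence means the
# table is not plain AFFN.
_COMPRESSED_RE = re.compile(r"[A-DF-Za-df-z@%]")


def _normalize_label(label: str) -> str:
    # JCAMP labels are compared ignoring case, spaces, dashes and underscores
    return re.sub(r"[ \-_/]", "", label).upper()


def _parse_ldrs(text: str) -> dict[str, str]:
    """Split a JCAMP block into normalized label -> content (with line joins)."""
    ldrs: dict[str, str] = {}
    current: str | None = None
    lines: list[str] = []
    for raw_line in text.splitlines():
        # strip inline comments ($$ ...)
        line = raw_line.split("$$")[0].rstrip()
        m = _LDR_RE.match(line)
        if m:
            if current is not None and current not in ldrs:
                ldrs[current] = "\n".join(lines)
            current = _normalize_label(m.group(1))
            lines = [m.group(2)]
        elif current is not None:
            lines.append(line)
    if current is not None and current not in ldrs:
        ldrs[current] = "\n".join(lines)
    return ldrs


def _decode_xypoints(body: str) -> tuple[np.ndarray, np.ndarray]:
    nums = [float(t) for t in _NUM_RE.findall(body)]
    if len(nums) < 4:
        raise JcampParseError("##XYPOINTS: fewer than two (X,Y) pairs")
    if len(nums) % 2 != 0:
        raise JcampParseError("##XYPOINTS: odd number of values")
    arr = np.asarray(nums, dtype=float).reshape(-1, 2)
    return arr[:, 0], arr[:, 1]


def _decode_xydata(body: str) -> tuple[np.ndarray, np.ndarray]:
    """Decode an AFFN (X++(Y..Y)) table: each line starts with X, then Ys."""
    xs: list[float] = []
    ys: list[float] = []
    lines = [ln for ln in body.splitlines() if ln.strip()]
    if not lines:
        raise JcampParseError("##XYDATA: empty table")
    # first line is the variable list, e.g. "(X++(Y..Y))"
    if "(" in lines[0] and "+" in lines[0]:
        lines = lines[1:]
    for lineno, line in enumerate(lines, start=1):
        if _COMPRESSED_RE.search(line):
            raise JcampParseError(
                f"##XYDATA line {lineno}: SQZ/DIF/DUP compression not supported"
            )
        nums = [float(t) for t in _NUM_RE.findall(line)]
        if len(nums) < 2:
            raise JcampParseError(f"##XYDATA line {lineno}: no ordinate values")
        x0, yvals = nums[0], nums[1:]
        xs.append((x0, len(yvals)))  # type: ignore[arg-type]
        ys.extend(yvals)
    # reconstruct abscissa: within a line, X advances by the global increment
    total_y = len(ys)
    if len(xs) >= 2:
        # increment from consecutive line starts
        (xa, na), (xb, _) = xs[0], xs[1]
        dx = (xb - xa) / na
    else:
        dx = None
    all_x: list[float] = []
    for x0, ny in xs:  # type: ignore[misc]
        if dx is None:
            # single line: spacing unknown unless only 1 y per... fall back to
            # FIRSTX/LASTX handled by caller; here assume unit spacing
            raise JcampParseError(
                "##XYDATA: cannot infer abscissa increment from a single line; "
                "need FIRSTX/LASTX/NPOINTS"
            )
        all_x.extend(x0 + i * dx for i in range(ny))
    if len(all_x) != total_y:
        raise JcampParseError("##XYDATA: abscissa reconstruction mismatch")
    return np.asarray(all_x, dtype=float), np.asarray(ys, dtype=float)


def read_jcampdx(path: str | Path) -> RawSpectrum:
    """Parse a single-block JCAMP-DX file into a :class:`RawSpectrum`.

    XFACTOR/YFACTOR are applied, descending abscissae are reversed so the
    result is ascending, and duplicate wavenumbers keep the first occurrence
    (with a warning).

    Raises
    ------
    JcampParseError
        Missing or malformed required labels, unsupported encodings, or an
        ``##NPOINTS`` mismatch of more than one point.
    JcampDataError
        Non-finite decoded values.
    """
    path = Path(path)
    text = path.read_text()
    ldrs = _parse_ldrs(text)
    if "TITLE" not in ldrs:
        raise JcampParseError(f"{path}: missing ##TITLE label")

    yunits = ldrs.get("YUNITS", "ABSORBANCE").strip().upper()
    if yunits and yunits != "ABSORBANCE":
        raise JcampParseError(
            f"{path}: ##YUNITS={yunits!r} not supported (expected ABSORBANCE)"
        )

    if "XYPOINTS" in ldrs:
        body = ldrs["XYPOINTS"]
        # drop the variable-list line "(XY..XY)" if present
        body = re.sub(r"\(\s*XY\.\.XY\s*\)", "", body, count=1)
        x, y = _decode_xypoints(body)
    elif "XYDATA" in ldrs:
        try:
            x, y = _decode_xydata(ldrs["XYDATA"])
        except JcampParseError:
            # single-line tables can still be decoded via FIRSTX/LASTX
            x, y = _decode_xydata_with_range(ldrs)
    else:
        raise JcampParseError(f"{path}: missing ##XYDATA or ##XYPOINTS label")

    xfactor = float(ldrs.get("XFACTOR", "1") or 1)
    yfactor = float(ldrs.get("YFACTOR", "1") or 1)
    x = x * xfactor
    y = y * yfactor

    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        bad = int(np.flatnonzero(~(np.isfinite(x) & np.isfinite(y)))[0])
        raise JcampDataError(f"{path}: non-finite value at data point {bad}")

    if "NPOINTS" in ldrs:
        declared = int(float(ldrs["NPOINTS"].strip()))
        if abs(declared - len(x)) > 1:
            raise JcampParseError(
                f"{path}: ##NPOINTS={declared} but decoded {len(x)} points"
            )

    # canonicalize: ascending abscissa
    if len(x) >= 2 and x[0] > x[-1]:
        x = x[::-1]
        y = y[::-1]
    order = np.argsort(x, kind="stable")
    x = x[order]
    y = y[order]
    # duplicates: keep first occurrence
    keep = np.concatenate(([True], np.diff(x) > 0))
    if not keep.all():
        logger.warning(
            "%s: %d duplicate wavenumber(s) dropped (kept first)",
            path,
            int((~keep).sum()),
        )
        x = x[keep]
        y = y[keep]

    meta = {
        k.lower(): ldrs[k].strip()
        for k in ("TITLE", "DATE", "SPECTROMETERDATASYSTEM", "ORIGIN", "OWNER")
        if k in ldrs and ldrs[k].strip()
    }
    return RawSpectrum(
        sample_id=meta.get("title", path.stem),
        wavenumbers=x,
        absorbances=y,
        source_path=str(path),
        meta=meta,
    )


def _decode_xydata_with_range(ldrs: dict[str, str]) -> tuple[np.ndarray, np.ndarray]:
    """Fallback (X++(Y..Y)) decode using FIRSTX/LASTX/NPOINTS for the grid."""
    for lbl in ("FIRSTX", "LASTX", "NPOINTS"):
        if lbl not in ldrs:
            raise JcampParseError(f"##XYDATA single-line table needs ##{lbl}")
    firstx = float(ldrs["FIRSTX"])
    lastx = float(ldrs["LASTX"])
    npoints = int(float(ldrs["NPOINTS"]))
    body = ldrs["XYDATA"]
    lines = [ln for ln in body.splitlines() if ln.strip()]
    if lines and "(" in lines[0] and "+" in lines[0]:
        lines = lines[1:]
    ys: list[float] = []
    for line in lines:
        nums = [float(t) for t in _NUM_RE.findall(line)]
        ys.extend(nums[1:])  # first number on each line is X
    if abs(len(ys) - npoints) > 1:
        raise JcampParseError(
            f"##NPOINTS={npoints} but decoded {len(ys)} ordinates"
        )
    x = np.linspace(firstx, lastx, len(ys))
    return x, np.asarray(ys, dtype=float)


def write_jcampdx(spectrum: RawSpectrum, path: str | Path) -> None:
    """Write a minimal valid JCAMP-DX 4.24 block with an XYPOINTS table.

    ``read_jcampdx(write_jcampdx(s))`` reproduces ``s`` to within 1e-9.
    """
    path = Path(path)
    x = spectrum.wavenumbers
    y = spectrum.absorbances
    lines = [
        f"##TITLE={spectrum.sample_id}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        "##XFACTOR=1",
        "##YFACTOR=1",
        f"##FIRSTX={x[0]:.10g}",
        f"##LASTX={x[-1]:.10g}",
        f"##NPOINTS={len(x)}",
        "##XYPOINTS=(XY..XY)",
    ]
    lines.extend(f"{float(xi)!r}, {float(yi)!r}" for xi, yi in zip(x, y))
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")
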