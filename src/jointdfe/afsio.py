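"""Reading and writing joint spectra in the dadi frequency-spectrum text dialect.

Format: optional ``#`` comment lines, then a header line
``"d1 d2 [folded|unfolded]"`` with ``d = n + 1`` per axis, then the
whitespace-separated flattened values in row-major order, then a line of
``d1*d2`` 0/1 mask flags (1 = masked).  Round-trips are bit-exact: floats
are written with 17 significant digits.
"""

from __future__ import annotations

import os

import numpy as np

from .spectrum import JointSpectrum, SampleConfig, SpectrumError


class AFSParseError(SpectrumError):
    """Malformed AFS file; message carries the offending line number."""


def read_afs(path: str | os.PathLike) -> JointSpectrum:
    """Read a 2D frequency spectrum from a dadi-format text file."""
    tokens: list[str] = []
    header: list[str] | None = None
    header_lineno = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if header is None:
                header = stripped.split()
                header_lineno = lineno
                continue
            tokens.extend(stripped.split())
    if header is None:
        raise AFSParseError(f"{path}: no header line found")
    if len(header) < 2:
        raise AFSParseError(
            f"{path}:{header_lineno}: header needs 'd1 d2 [folded|unfolded]'"
        )
    try:
        d1, d2 = int(header[0]), int(header[1])
    except ValueError as exc:
        raise AFSParseError(
            f"{path}:{header_lineno}: non-integer dimensions {header[:2]}"
        ) from exc
    folding = header[2] if len(header) > 2 else "unfolded"
    if folding not in ("folded", "unfolded"):
        raise AFSParseError(
            f"{path}:{header_lineno}: folding flag must be 'folded' or "
            f"'unfolded', got {folding!r}"
        )
    if folding == "folded":
        raise AFSParseError(f"{path}: folded spectra are not supported")
    size = d1 * d2
    if len(tokens) not in (size, 2 * size):
        raise AFSParseError(
            f"{path}: expected {size} values (+ optional {size} mask flags), "
            f"got {len(tokens)} tokens"
        )
    try:
        values = np.array([float(t) for t in tokens[:size]]).reshape(d1, d2)
    except ValueError as exc:
        raise AFSParseError(f"{path}: non-numeric spectrum entry") from exc
    mask = None
    if len(tokens) == 2 * size:
        flags = tokens[size:]
        if any(t not in ("0", "1") for t in flags):
            raise AFSParseError(f"{path}: mask line must contain only 0/1")
        mask = np.array([t == "1" for t in flags]).reshape(d1, d2)
    sample = SampleConfig(d1 - 1, d2 - 1)
    return JointSpectrum(values, sample, mask=mask, kind="observed")


def write_afs(spec: JointSpectrum, path: str | os.PathLike,
              comment: str | None = None) -> None:
    """Write a spectrum in the dadi text dialect (17 significant digits)."""
    d1, d2 = spec.shape
    with open(path, "w") as fh:
        fh.write("# jointdfe frequency spectrum\n")
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"{d1} {d2} unfolded\n")
        flat = spec.values.ravel()
        fh.write(" ".join(f"{float(v):.17g}" for v in flat) + "\n")
        fh.write(" ".join("1" if m else "0" for m in spec.mask.ravel()) + "\n")
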