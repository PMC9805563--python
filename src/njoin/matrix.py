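"""Lower-triangular distance matrices and PHYLIP distance-matrix I/O.

The on-disk dialects are the two PHYLIP distance-matrix flavours common in
distance-based phylogenetics:

``relaxed_lower``
    First non-blank line: taxon count ``n``.  Then one line per taxon: the
    taxon name (any whitespace-free token, no 10-column limit) followed by the
    distances to all previously listed taxa.  Row ``i`` (0-based) therefore
    carries ``i`` values; the first taxon line carries none.

``full``
    Same header, then ``n`` lines of ``name d_0 ... d_{n-1}`` forming a square
    symmetric matrix with a zero diagonal.  On read the matrix is checked for
    symmetry and only the lower triangle is retained.

Either dialect may arrive gzip-compressed; compression is detected from the
leading magic bytes, never from the file name.

Distances can be held at ``double`` (float64), ``float`` (float32), ``uint16``
or ``uint8`` precision.  In the integer modes each stored cell is a
quantization level and the true distance is ``cell * scale``; row sums and
join criteria downstream are always accumulated in double precision regardless
of the storage mode.
"""

from __future__ import annotations

import gzip
import io
import itertools
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np

from .errors import PhylipParseError, ValidationError

__all__ = [
    "DistanceMatrix",
    "read_phylip",
    "write_phylip",
    "quantize",
    "four_point_violation",
    "triangle_violation",
]

#: quantization levels per integer precision mode
QUANT_LEVELS = {"uint8": 255, "uint16": 65535}

_DTYPES = {
    "double": np.float64,
    "float": np.float32,
    "uint8": np.uint8,
    "uint16": np.uint16,
}

#: symmetry tolerance for full-dialect input, relative to max |D|
ASYM_RTOL = 1e-6


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


class DistanceMatrix:
    """Pairwise distances stored as a ragged lower triangle.

    Parameters
    ----------
    labels
        Unique taxon names, one per row, in storage order.
    rows
        ``rows[i]`` holds the ``i`` distances from taxon ``i`` to taxa
        ``0..i-1`` (row 0 is empty).  In the integer precision modes the
        entries are quantization cells; otherwise they are the distances
        themselves.
    precision
        One of ``double``, ``float``, ``uint16``, ``uint8``.
    scale
        Positive dequantization factor; must be 1.0 in the floating modes.
    """

    def __init__(
        self,
        labels: Sequence[str],
        rows: Iterable[np.ndarray],
        precision: str = "double",
        scale: float = 1.0,
        validate: bool = True,
    ):
        if precision not in _DTYPES:
            raise ValidationError(f"unknown precision mode {precision!r}")
        self.labels: list[str] = [str(x) for x in labels]
        dtype = _DTYPES[precision]
        self.rows: list[np.ndarray] = [np.asarray(r, dtype=dtype) for r in rows]
        self.precision = precision
        self.scale = float(scale)
        if validate:
            self.validate()

    # -- basic protocol ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<DistanceMatrix n={self.n} precision={self.precision}>"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistanceMatrix):
            return NotImplemented
        return (
            self.labels == other.labels
            and self.precision == other.precision
            and self.scale == other.scale
            and all(np.array_equal(a, b) for a, b in zip(self.rows, other.rows))
        )

    # -- accessors ---------------------------------------------------------

    def value(self, i: int, k: int) -> float:
        """True distance between taxa ``i`` and ``k`` (order-free)."""
        if i == k:
            return 0.0
        i, k = (i, k) if i > k else (k, i)
        return float(self.rows[i][k]) * self.scale

    def max_value(self) -> float:
        vals = [r.max() for r in self.rows if r.size]
        return float(max(vals)) * self.scale if vals else 0.0

    def to_square(self) -> np.ndarray:
        """Dense symmetric matrix of true distances, float64, zero diagonal."""
        n = self.n
        sq = np.zeros((n, n), dtype=np.float64)
        for i in range(1, n):
            row = self.rows[i].astype(np.float64) * self.scale
            sq[i, :i] = row
            sq[:i, i] = row
        return sq

    @classmethod
    def from_square(
        cls, labels: Sequence[str], sq: np.ndarray, precision: str = "double"
    ) -> "DistanceMatrix":
        sq = np.asarray(sq, dtype=np.float64)
        rows = [sq[i, :i].copy() for i in range(len(labels))]
        return cls(labels, rows, precision=precision)

    def copy(self) -> "DistanceMatrix":
        return DistanceMatrix(
            list(self.labels),
            [r.copy() for r in self.rows],
            precision=self.precision,
            scale=self.scale,
            validate=False,
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        n = self.n
        if len(self.rows) != n:
            raise ValidationError(f"{n} labels but {len(self.rows)} rows")
        if len(set(self.labels)) != n:
            raise ValidationError("taxon labels are not unique")
        if self.scale <= 0:
            raise ValidationError("scale must be positive")
        if self.precision in ("double", "float") and self.scale != 1.0:
            raise ValidationError("scale must be 1.0 in floating precision modes")
        for i, row in enumerate(self.rows):
            if row.size != i:
                raise ValidationError(f"row {i} stores {row.size} entries, expected {i}")
            if row.size and self.precision in ("double", "float") and np.any(row < 0):
                raise ValidationError(f"negative distance in row {i}")


# ---------------------------------------------------------------------------
# PHYLIP reading / writing
# ---------------------------------------------------------------------------


def _open_text(source: str | Path | IO) -> IO[str]:
    """Open ``source`` for text reading, transparently inflating gzip.

    Compression is recognised by the 0x1f 0x8b magic bytes, independent of the
    file name.
    """
    if isinstance(source, (str, Path)):
        raw: IO[bytes] = open(source, "rb")
    elif isinstance(source, io.TextIOBase):
        return source
    else:
        raw = source
    head = raw.read(2)
    raw.seek(raw.tell() - len(head))
    if head == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="utf-8")
    return io.TextIOWrapper(raw, encoding="utf-8")


def read_phylip(
    source: str | Path | IO, dialect: str = "relaxed_lower"
) -> DistanceMatrix:
    """Parse a PHYLIP distance matrix.

    Parameters
    ----------
    source
        Path or binary/text stream; gzip input is auto-detected.
    dialect
        ``relaxed_lower`` or ``full``.

    Raises
    ------
    PhylipParseError
        Header/row shape problems, naming the offending line.
    ValidationError
        Negative distances, or asymmetry beyond tolerance in ``full`` input.
    """
    if dialect not in ("relaxed_lower", "full"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    fh = _open_text(source)
    lines = [(no + 1, ln.strip()) for no, ln in enumerate(fh) if ln.strip()]
    if not lines:
        raise PhylipParseError("empty input: missing taxon-count header")
    hdr_no, hdr = lines[0]
    try:
        n = int(hdr.split()[0])
    except ValueError:
        raise PhylipParseError(f"line {hdr_no}: taxon count expected, got {hdr!r}") from None
    if n < 1:
        raise PhylipParseError(f"line {hdr_no}: taxon count must be >= 1")
    body = lines[1:]
    if len(body) != n:
        raise PhylipParseError(
            f"header declares {n} taxa but {len(body)} taxon lines found"
        )

    labels: list[str] = []
    rows: list[np.ndarray] = []
    expected = (lambda i: i) if dialect == "relaxed_lower" else (lambda i: n)
    parsed: list[np.ndarray] = []
    for i, (no, ln) in enumerate(body):
        toks = ln.split()
        name, vals = toks[0], toks[1:]
        want = expected(i)
        if len(vals) != want:
            raise PhylipParseError(
                f"line {no}: taxon {name!r} has {len(vals)} distances, expected {want}"
            )
        try:
            arr = np.array([float(v) for v in vals], dtype=np.float64)
        except ValueError:
            raise PhylipParseError(f"line {no}: non-numeric distance for taxon {name!r}") from None
        if arr.size and np.any(arr < 0):
            raise ValidationError(f"line {no}: negative distance for taxon {name!r}")
        labels.append(name)
        parsed.append(arr)

    if dialect == "full":
        sq = np.vstack(parsed) if n > 1 else np.zeros((1, 1))
        tol = ASYM_RTOL * (np.abs(sq).max() if sq.size else 0.0)
        if np.abs(sq - sq.T).max() > tol:
            raise ValidationError(
                f"full matrix asymmetric beyond tolerance {tol:g}"
            )
        rows = [sq[i, :i].copy() for i in range(n)]
    else:
        rows = parsed
    return DistanceMatrix(labels, rows, precision="double")


def _format(v: float) -> str:
    return format(float(v), ".17g")


def write_phylip(
    m: DistanceMatrix, sink: str | Path | IO, dialect: str = "relaxed_lower"
) -> None:
    """Write ``m`` in the requested dialect.

    Distances are written dequantized (``cell * scale``) with enough digits
    that a double-precision matrix round-trips exactly.  A path ending in
    ``.gz`` is gzip-compressed.
    """
    if dialect not in ("relaxed_lower", "full"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    out = [str(m.n)]
    if dialect == "relaxed_lower":
        for i, label in enumerate(m.labels):
            row = m.rows[i].astype(np.float64) * m.scale
            out.append(" ".join([label] + [_format(v) for v in row]))
    else:
        sq = m.to_square()
        for i, label in enumerate(m.labels):
            out.append(" ".join([label] + [_format(v) for v in sq[i]]))
    text = "\n".join(out) + "\n"
    if isinstance(sink, (str, Path)):
        if str(sink).endswith(".gz"):
            with gzip.open(sink, "wt", encoding="utf-8") as fh:
                fh.write(text)
        else:
            Path(sink).write_text(text, encoding="utf-8")
    else:
        sink.write(text)


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------


def quantize(
    m: DistanceMatrix, precision: str, scale: float | None = None
) -> DistanceMatrix:
    """Quantize a floating-precision matrix to ``uint8`` or ``uint16`` cells.

    By default the full range of levels is used: ``scale = max(D) / L`` with
    ``L = 255`` (uint8) or ``65535`` (uint16) and each cell set to
    ``round_half_up(d / scale)``, so dequantized values deviate from the
    originals by at most ``scale / 2``.  Passing ``scale`` explicitly pins the
    grid instead (e.g. ``scale=1`` embeds an integer-valued matrix
    identically).
    """
    if precision not in QUANT_LEVELS:
        raise ValidationError(f"quantize target must be uint8/uint16, got {precision!r}")
    if m.precision not in ("double", "float"):
        raise ValidationError("quantize expects a floating-precision matrix")
    levels = QUANT_LEVELS[precision]
    if scale is None:
        top = m.max_value()
        if top <= 0:
            raise ValidationError("cannot quantize an all-zero matrix: scale undefined")
        scale = top / levels
    elif scale <= 0:
        raise ValidationError("scale must be positive")
    rows = []
    for r in m.rows:
        cells = _round_half_up(r.astype(np.float64) / scale)
        if np.any(cells > levels) or np.any(cells < 0):
            raise ValidationError(
                f"distances exceed the {precision} range at scale {scale:g}"
            )
        rows.append(cells)
    return DistanceMatrix(m.labels, rows, precision=precision, scale=scale)


def integer_preserving_scale(m: DistanceMatrix, precision: str) -> float:
    """Scale the CLI uses for ``--precision``: 1.0 when every distance is an
    integer within the level range (identity embedding), else ``max(D)/L``."""
    levels = QUANT_LEVELS[precision]
    vals = np.concatenate([r.astype(np.float64) for r in m.rows if r.size] or [np.zeros(0)])
    if vals.size and np.all(vals == np.floor(vals)) and vals.max() <= levels:
        return 1.0
    top = m.max_value()
    if top <= 0:
        raise ValidationError("cannot quantize an all-zero matrix: scale undefined")
    return top / levels


# ---------------------------------------------------------------------------
# Metricity audits
# ---------------------------------------------------------------------------


def four_point_violation(m: DistanceMatrix) -> float:
    """Largest four-point-condition violation over all quartets.

    For each quartet the three pairwise sums ``D(i,j)+D(k,l)``,
    ``D(i,k)+D(j,l)``, ``D(i,l)+D(j,k)`` are formed; additivity requires the
    two largest to be equal, and the violation is their difference.  Returns 0
    for an exactly additive matrix.  O(n^4): intended for small audits.
    """
    sq = m.to_square()
    worst = 0.0
    for i, j, k, l in itertools.combinations(range(m.n), 4):
        s = sorted((sq[i, j] + sq[k, l], sq[i, k] + sq[j, l], sq[i, l] + sq[j, k]))
        worst = max(worst, s[2] - s[1])
    return worst


def triangle_violation(m: DistanceMatrix) -> float:
    """Largest triangle-inequality violation ``D(i,k) - D(i,j) - D(j,k)``
    over all triples; <= 0 means the matrix is metric."""
    sq = m.to_square()
    worst = -np.inf
    for j in range(m.n):
        worst = max(worst, float((sq - sq[:, [j]] - sq[[j], :]).max()))
    return worst
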