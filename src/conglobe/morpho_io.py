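"""Readers and writers for the study's standard file formats.

Supported formats:

* TPS landmark files (the dialect produced by tps-DIG: ``LM``, ``CURVES``,
  ``POINTS``, ``ID``, ``IMAGE``, ``SCALE`` keys; unknown keys are skipped with
  a logged warning),
* Newick trees (parsed with dendropy, converted to :class:`~conglobe.phylogeny.Phylogeny`
  with deterministic preorder node IDs and default branch length 1),
* a TNT/NEXUS subset for morphological character matrices with ``?`` (missing)
  and ``-`` (inapplicable) codes kept distinct.

Also provides arc-length resampling of digitised curves into fixed numbers of
semilandmarks.
"""
from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .errors import DegenerateInputError, FormatError
from .phylogeny import Phylogeny

logger = logging.getLogger(__name__)

TRAITS = ("head", "pronotum", "elytra")
VIEWS = ("dorsal", "lateral")

# default semilandmark counts per trait: head 30, pronotum 50, elytra 50
DEFAULT_SEMILANDMARKS = {"head": 30, "pronotum": 50, "elytra": 50}


@dataclass
class Curve:
    """An ordered digitised polyline."""

    points: np.ndarray  # (m, 2)
    closed: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise FormatError("curve points must be an (m, 2) array")
        if len(self.points) < 2:
            raise DegenerateInputError("curve needs at least 2 vertices")
        if self.arc_length() <= 0:
            raise DegenerateInputError("curve has zero total arc length")

    def arc_length(self) -> float:
        seg = np.diff(self.points, axis=0)
        total = float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
        if self.closed:
            total += float(np.hypot(*(self.points[0] - self.points[-1])))
        return total


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2-D landmark/semilandmark set for one trait."""

    specimen_id: str
    points: np.ndarray  # (k, 2)
    trait: str | None = None
    view: str | None = None
    scale: float | None = None
    curves: list[Curve] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.points)):
            raise FormatError(f"{self.specimen_id}: non-finite coordinates")
        if len(self.points) < 3 and not self.curves:
            raise FormatError(
                f"{self.specimen_id}: a configuration needs >=3 points "
                "(or attached curves awaiting resampling)"
            )
        if self.trait is not None and self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.view is not None and self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def with_points(self, points: np.ndarray) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            self.specimen_id, points, self.trait, self.view, self.scale, list(self.curves)
        )


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

_TPS_KEY = re.compile(r"^([A-Z]+)\s*=\s*(.*)$")


def _parse_xy(line: str, lineno: int) -> tuple[float, float]:
    parts = line.split()
    if len(parts) != 2:
        raise FormatError(f"line {lineno}: expected 'x y', got {line!r}")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-numeric coordinate in {line!r}") from exc


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Read a TPS file into landmark configurations.

    Each ``LM=`` block starts a record.  ``CURVES=``/``POINTS=`` blocks attach
    digitised curves for later resampling; ``SCALE`` (units per image unit) is
    applied multiplicatively to all coordinates of the record.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    records: list[LandmarkConfiguration] = []

    i = 0
    n_lines = len(lines)

    def peek_key(idx: int) -> tuple[str, str] | None:
        if idx >= n_lines:
            return None
        m = _TPS_KEY.match(lines[idx].strip())
        return (m.group(1), m.group(2)) if m else None

    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        key = peek_key(i)
        if key is None or key[0] != "LM":
            raise FormatError(f"line {i + 1}: expected LM= record start, got {lines[i]!r}")
        try:
            n_lm = int(key[1])
        except ValueError as exc:
            raise FormatError(f"line {i + 1}: bad LM count {key[1]!r}") from exc
        i += 1
        pts = []
        for _ in range(n_lm):
            if i >= n_lines or peek_key(i) is not None:
                raise FormatError(f"line {i + 1}: record declares LM={n_lm} but has fewer points")
            pts.append(_parse_xy(lines[i].strip(), i + 1))
            i += 1
        curves: list[Curve] = []
        specimen_id = f"specimen_{len(records) + 1}"
        scale: float | None = None
        while True:
            key = peek_key(i)
            if key is None:
                if i < n_lines and lines[i].strip():
                    raise FormatError(f"line {i + 1}: unexpected content {lines[i]!r}")
                if i >= n_lines:
                    break
                i += 1
                continue
            name, value = key
            if name == "LM":
                break
            i += 1
            if name == "CURVES":
                n_curves = int(value)
                for _ in range(n_curves):
                    pk = peek_key(i)
                    if pk is None or pk[0] != "POINTS":
                        raise FormatError(f"line {i + 1}: expected POINTS= inside CURVES block")
                    n_pts = int(pk[1])
                    i += 1
                    cpts = []
                    for _ in range(n_pts):
                        if i >= n_lines or peek_key(i) is not None:
                            raise FormatError(
                                f"line {i + 1}: curve declares POINTS={n_pts} but has fewer vertices"
                            )
                        cpts.append(_parse_xy(lines[i].strip(), i + 1))
                        i += 1
                    curves.append(Curve(np.asarray(cpts)))
            elif name == "POINTS":
                raise FormatError(f"line {i}: POINTS= outside a CURVES block")
            elif name == "ID":
                specimen_id = value.strip() or specimen_id
            elif name == "SCALE":
                scale = float(value)
            elif name == "IMAGE":
                pass  # provenance only
            else:
                logger.warning("TPS line %d: ignoring unknown key %s=", i, name)
        pts_arr = np.asarray(pts, dtype=float).reshape(-1, 2)
        if scale is not None:
            pts_arr = pts_arr * scale
            curves = [Curve(c.points * scale, c.closed) for c in curves]
        records.append(
            LandmarkConfiguration(specimen_id, pts_arr, scale=scale, curves=curves)
        )
    return records


def write_tps(configs: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations to a TPS file (LM, CURVES/POINTS, ID, SCALE keys)."""
    buf = io.StringIO()
    for cfg in configs:
        buf.write(f"LM={cfg.n_points}\n")
        for x, y in cfg.points:
            buf.write(f"{x:.6f} {y:.6f}\n")
        if cfg.curves:
            buf.write(f"CURVES={len(cfg.curves)}\n")
            for curve in cfg.curves:
                buf.write(f"POINTS={len(curve.points)}\n")
                for x, y in curve.points:
                    buf.write(f"{x:.6f} {y:.6f}\n")
        buf.write(f"ID={cfg.specimen_id}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# curve resampling
# ---------------------------------------------------------------------------


def resample_curve(curve: Curve, n: int) -> np.ndarray:
    """Resample a polyline into ``n`` semilandmarks equally spaced by arc length.

    Open curves keep their endpoints; closed curves are sampled at spacing
    L/n starting from the first vertex.  Interpolation is linear along the
    polyline, matching the resolution of hand-digitised curves (no spline).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    pts = curve.points
    if curve.closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seglen.sum())
    if total <= 0:
        raise DegenerateInputError("cannot resample a zero-length curve")
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    if curve.closed:
        targets = np.arange(n) * total / n
    else:
        targets = np.linspace(0.0, total, n)
    x = np.interp(targets, cum, pts[:, 0])
    y = np.interp(targets, cum, pts[:, 1])
    out = np.column_stack([x, y])
    if not curve.closed:
        out[0], out[-1] = pts[0], pts[-1]
    return out


def semilandmarks_from_tps(
    configs: Sequence[LandmarkConfiguration],
    trait: str,
    n: int | None = None,
    view: str | None = None,
) -> list[LandmarkConfiguration]:
    """Resample each record's first curve into the trait's semilandmark count."""
    n = n if n is not None else DEFAULT_SEMILANDMARKS[trait]
    out = []
    for cfg in configs:
        if not cfg.curves:
            raise FormatError(f"{cfg.specimen_id}: no curve to resample")
        pts = resample_curve(cfg.curves[0], n)
        out.append(LandmarkConfiguration(cfg.specimen_id, pts, trait=trait, view=view))
    return out


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------


def read_newick(source: str | Path) -> Phylogeny:
    """Read a Newick tree; missing branch lengths default to 1 (the
    equal-branch-length convention) and node IDs are assigned in preorder
    with root = 1."""
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"malformed Newick: {exc}") from exc
    parent: dict[int, int | None] = {}
    tips: dict[int, str] = {}
    lengths: dict[int, float] = {}
    counter = [0]

    def walk(dnode, par: int | None) -> None:
        counter[0] += 1
        me = counter[0]
        parent[me] = par
        if dnode.edge.length is not None:
            lengths[me] = float(dnode.edge.length)
        if dnode.is_leaf():
            if dnode.taxon is None:
                raise FormatError("unlabelled tip in Newick input")
            tips[me] = dnode.taxon.label
        for child in dnode.child_nodes():
            walk(child, me)

    walk(dtree.seed_node, None)
    return Phylogeny(parent, lengths, tips)


def write_newick(tree: Phylogeny, path: str | Path | None = None) -> str:
    text = tree.to_newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# character matrices (TNT / NEXUS subset)
# ---------------------------------------------------------------------------

MISSING = "?"
INAPPLICABLE = "-"
_STATE_SYMBOLS = set("0123456789")


@dataclass
class CharacterMatrix:
    """Taxa x unordered multistate morphological characters.

    Cells hold single state symbols ``0``..``9``, ``?`` (missing) or ``-``
    (inapplicable); the two non-state codes are kept distinct on round-trips.
    """

    taxa: list[str]
    cells: np.ndarray  # (n_taxa, n_chars) of unicode symbols

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype="<U1")
        if self.cells.ndim != 2:
            raise FormatError("matrix cells must be 2-D")
        if len(self.taxa) != self.cells.shape[0]:
            raise FormatError("taxon count does not match matrix rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise FormatError("taxon labels are not unique")
        bad = set(self.cells.ravel()) - _STATE_SYMBOLS - {MISSING, INAPPLICABLE}
        if bad:
            raise FormatError(f"unknown state symbols: {sorted(bad)}")

    @property
    def n_taxa(self) -> int:
        return self.cells.shape[0]

    @property
    def n_characters(self) -> int:
        return self.cells.shape[1]

    def column(self, i: int) -> dict[str, str]:
        return {t: self.cells[j, i] for j, t in enumerate(self.taxa)}

    def observed_states(self, i: int) -> set[str]:
        return set(self.cells[:, i]) & _STATE_SYMBOLS


def read_matrix(path: str | Path, dialect: str = "tnt") -> CharacterMatrix:
    """Read a TNT ``xread`` block or a minimal NEXUS DATA/CHARACTERS block."""
    text = Path(path).read_text()
    if dialect == "tnt":
        return _read_tnt(text)
    if dialect == "nexus":
        return _read_nexus(text)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_rows(lines: list[str], ntax: int, nchar: int) -> CharacterMatrix:
    taxa, rows = [], []
    for line in lines:
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise FormatError(f"bad matrix row: {line!r}")
        name, states = parts[0], parts[1].replace(" ", "")
        if len(states) != nchar:
            raise FormatError(
                f"taxon {name!r}: {len(states)} states, header declares {nchar}"
            )
        taxa.append(name)
        rows.append(list(states))
    if len(taxa) != ntax:
        raise FormatError(f"{len(taxa)} taxa found, header declares {ntax}")
    return CharacterMatrix(taxa, np.asarray(rows))


def _read_tnt(text: str) -> CharacterMatrix:
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("'")]
    if not lines or not lines[0].lower().startswith("xread"):
        raise FormatError("TNT file must start with 'xread'")
    rest = lines[0][5:].split() + lines[1:]
    nums = []
    idx = 0
    while len(nums) < 2 and idx < len(rest):
        for token in str(rest[idx]).split():
            if token.isdigit():
                nums.append(int(token))
        idx += 1
    if len(nums) < 2:
        raise FormatError("TNT header must declare nchar and ntax")
    nchar, ntax = nums[0], nums[1]  # TNT order: characters first
    body = [str(x) for x in rest[idx:]]
    body = [ln for ln in body if ln and ln != ";"]
    if body and body[-1].endswith(";"):
        body[-1] = body[-1][:-1].strip()
        body = [ln for ln in body if ln]
    return _read_rows(body, ntax, nchar)


def _read_nexus(text: str) -> CharacterMatrix:
    m = re.search(r"dimensions\s+ntax\s*=\s*(\d+)\s+nchar\s*=\s*(\d+)", text, re.I)
    if not m:
        raise FormatError("NEXUS file lacks a DIMENSIONS line")
    ntax, nchar = int(m.group(1)), int(m.group(2))
    mm = re.search(r"matrix(.*?);", text, re.I | re.S)
    if not mm:
        raise FormatError("NEXUS file lacks a MATRIX block")
    body = [ln.strip() for ln in mm.group(1).splitlines() if ln.strip()]
    return _read_rows(body, ntax, nchar)


def write_matrix(matrix: CharacterMatrix, path: str | Path, dialect: str = "tnt") -> None:
    buf = io.StringIO()
    if dialect == "tnt":
        buf.write(f"xread\n{matrix.n_characters} {matrix.n_taxa}\n")
        for i, taxon in enumerate(matrix.taxa):
            buf.write(f"{taxon} {''.join(matrix.cells[i])}\n")
        buf.write(";\n")
    elif dialect == "nexus":
        buf.write("#NEXUS\nBEGIN DATA;\n")
        buf.write(f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};\n")
        buf.write('FORMAT DATATYPE=STANDARD MISSING=? GAP=- SYMBOLS="0123456789";\n')
        buf.write("MATRIX\n")
        for i, taxon in enumerate(matrix.taxa):
            buf.write(f"{taxon} {''.join(matrix.cells[i])}\n")
        buf.write(";\nEND;\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    Path(path).write_text(buf.getvalue())
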