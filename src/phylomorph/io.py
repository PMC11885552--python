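"""Readers and writers for the file formats the pipeline touches.

* TPS landmark files (``LM=`` / ``ID=`` / ``SCALE=`` records, with an optional
  ``CURVES=`` block naming the sliding curves by 1-based landmark indices).
* Newick trees with branch lengths (via dendropy; one tree per file).
* Two-column delimited taxon → predation-strategy tables.

Missing landmarks are encoded either by the ``-1 -1`` sentinel convention or
by an explicit ``MISSING`` line; both are accepted and the convention used by
:func:`write_tps` is configurable.  Labels are matched exactly after trimming
whitespace and replacing internal spaces with underscores — no fuzzy matching.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tree import PhyloTree, TreeError

__all__ = [
    "FormatError",
    "LandmarkSet",
    "StrategyTable",
    "read_tps",
    "write_tps",
    "read_newick",
    "write_newick",
    "read_strategy_table",
    "write_strategy_table",
    "normalize_label",
    "check_taxon_join",
]

MISSING_SENTINEL = (-1.0, -1.0)


class FormatError(ValueError):
    """Raised for malformed input files."""


def normalize_label(label: str) -> str:
    return "_".join(str(label).strip().split())


@dataclass
class LandmarkSet:
    """Raw or aligned 2D landmark configurations for a set of specimens.

    ``curves`` lists the sliding curves as ordered tuples of 0-based landmark
    indices (curve endpoints included); the interior points of each curve are
    the semilandmarks that may slide during superimposition.  User-facing
    reports use 1-based indices.
    """

    specimen_ids: list[str]
    coords: np.ndarray  # (n, k, 2)
    curves: tuple[tuple[int, ...], ...] = ()
    missing: np.ndarray | None = None  # (n, k) bool
    scale: np.ndarray | None = None  # per-specimen scale factor, if given

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise FormatError("coords must have shape (n_specimens, n_landmarks, 2)")
        n, k, _ = self.coords.shape
        if len(self.specimen_ids) != n:
            raise FormatError("specimen_ids length does not match coords")
        if len(set(self.specimen_ids)) != n:
            raise FormatError("specimen ids must be unique")
        if self.missing is None:
            self.missing = np.zeros((n, k), dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != (n, k):
            raise FormatError("missing mask shape does not match coords")
        for curve in self.curves:
            for idx in curve:
                if not (0 <= idx < k):
                    raise FormatError(f"curve index {idx} outside [0, {k})")
        if self.scale is not None:
            self.scale = np.asarray(self.scale, dtype=float)

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    @property
    def semilandmarks(self) -> tuple[int, ...]:
        """Interior points of all curves (curve endpoints are treated as fixed)."""
        out: list[int] = []
        for curve in self.curves:
            out.extend(curve[1:-1])
        return tuple(out)

    def subset(self, ids) -> "LandmarkSet":
        idx = [self.specimen_ids.index(i) for i in ids]
        return LandmarkSet(
            [self.specimen_ids[i] for i in idx],
            self.coords[idx].copy(),
            self.curves,
            self.missing[idx].copy(),
            None if self.scale is None else self.scale[idx].copy(),
        )

    def complete_specimens(self) -> list[str]:
        return [
            sid
            for sid, row in zip(self.specimen_ids, self.missing)
            if not row.any()
        ]


@dataclass
class StrategyTable:
    """Taxon → predation-strategy (specialist / generalist) mapping."""

    mapping: dict[str, str]
    levels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        self.mapping = {normalize_label(k): str(v).strip() for k, v in self.mapping.items()}
        found = tuple(sorted(set(self.mapping.values())))
        if self.levels:
            extra = set(found) - set(self.levels)
            if extra:
                raise FormatError(f"labels outside declared levels: {sorted(extra)}")
        else:
            self.levels = found
        if len(self.levels) > 2:
            raise FormatError(f"more than two strategy levels found: {self.levels}")
        if not self.mapping:
            raise FormatError("strategy table is empty")

    def __getitem__(self, taxon: str) -> str:
        return self.mapping[normalize_label(taxon)]

    def counts(self) -> dict[str, int]:
        out = {lv: 0 for lv in self.levels}
        for v in self.mapping.values():
            out[v] += 1
        return out

    def taxa_with(self, level: str) -> list[str]:
        return sorted(t for t, v in self.mapping.items() if v == level)

    def validate_against(self, tree: PhyloTree) -> list[str]:
        """Check every tree tip is labelled; return taxa in the table but not the tree."""
        missing = [t for t in tree.tip_labels if normalize_label(t) not in self.mapping]
        if missing:
            raise FormatError(f"tree tips without a strategy label: {missing}")
        return [t for t in self.mapping if t not in {normalize_label(x) for x in tree.tip_labels}]


# --------------------------------------------------------------------- TPS

def read_tps(path, missing_sentinel: tuple[float, float] | None = MISSING_SENTINEL) -> LandmarkSet:
    """Read a TPS landmark file.

    Each record holds ``LM=<k>`` followed by ``k`` coordinate lines, an
    optional ``CURVES=<n>`` block of ``POINTS=i,j,...`` lines (1-based
    landmark indices per sliding curve), an ``ID=`` line and an optional
    ``SCALE=`` line (coordinates are multiplied by the scale when present).
    A coordinate line equal to the sentinel (default ``-1 -1``) or the word
    ``MISSING`` marks a missing landmark.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty TPS file")

    ids: list[str] = []
    all_coords: list[np.ndarray] = []
    all_missing: list[np.ndarray] = []
    scales: list[float | None] = []
    curves_spec: tuple[tuple[int, ...], ...] | None = None

    i = 0
    record = 0
    while i < len(lines):
        line = lines[i]
        if not line.upper().startswith("LM="):
            raise FormatError(f"{path}: expected LM= at line {i + 1}, got {line!r}")
        k = int(line.split("=", 1)[1])
        record += 1
        i += 1
        coords = np.zeros((k, 2))
        miss = np.zeros(k, dtype=bool)
        for j in range(k):
            if i >= len(lines):
                raise FormatError(f"{path}: record {record} truncated")
            tok = lines[i]
            if tok.upper() == "MISSING":
                miss[j] = True
                coords[j] = np.nan
            else:
                parts = tok.split()
                if len(parts) != 2:
                    raise FormatError(
                        f"{path}: record {record}, bad coordinate line {tok!r}"
                    )
                x, y = float(parts[0]), float(parts[1])
                if missing_sentinel is not None and (x, y) == missing_sentinel:
                    miss[j] = True
                    coords[j] = np.nan
                else:
                    coords[j] = (x, y)
            i += 1
        rec_curves: list[tuple[int, ...]] = []
        sid: str | None = None
        scale: float | None = None
        while i < len(lines) and not lines[i].upper().startswith("LM="):
            tag = lines[i]
            up = tag.upper()
            if up.startswith("CURVES="):
                n_curves = int(tag.split("=", 1)[1])
                i += 1
                for _ in range(n_curves):
                    if i >= len(lines) or not lines[i].upper().startswith("POINTS="):
                        raise FormatError(f"{path}: record {record}: malformed CURVES block")
                    idx = tuple(
                        int(v) - 1 for v in lines[i].split("=", 1)[1].replace(",", " ").split()
                    )
                    rec_curves.append(idx)
                    i += 1
                continue
            if up.startswith("ID="):
                sid = normalize_label(tag.split("=", 1)[1])
            elif up.startswith("SCALE="):
                scale = float(tag.split("=", 1)[1])
            elif up.startswith("IMAGE=") or up.startswith("COMMENT="):
                pass
            else:
                raise FormatError(f"{path}: record {record}: unrecognized line {tag!r}")
            i += 1
        if sid is None:
            sid = f"specimen_{record}"
        if scale is not None:
            coords = coords * scale
        ids.append(sid)
        all_coords.append(coords)
        all_missing.append(miss)
        scales.append(scale)
        if rec_curves:
            rc = tuple(rec_curves)
            if curves_spec is not None and rc != curves_spec:
                raise FormatError(f"{path}: inconsistent CURVES blocks (record {record})")
            curves_spec = rc

    ks = {c.shape[0] for c in all_coords}
    if len(ks) != 1:
        detail = {sid: c.shape[0] for sid, c in zip(ids, all_coords)}
        raise FormatError(f"{path}: inconsistent landmark counts across specimens: {detail}")
    scale_arr = (
        None
        if all(s is None for s in scales)
        else np.array([1.0 if s is None else s for s in scales])
    )
    return LandmarkSet(
        ids,
        np.stack(all_coords),
        curves_spec or (),
        np.stack(all_missing),
        scale_arr,
    )


def write_tps(
    landmarks: LandmarkSet,
    path,
    precision: int = 10,
    missing_style: str = "sentinel",
) -> None:
    """Write a TPS file readable by :func:`read_tps`.

    ``missing_style`` selects the ``-1 -1`` sentinel (default) or explicit
    ``MISSING`` lines for masked landmarks.
    """
    if missing_style not in {"sentinel", "keyword"}:
        raise ValueError("missing_style must be 'sentinel' or 'keyword'")
    path = Path(path)
    out: list[str] = []
    for s, sid in enumerate(landmarks.specimen_ids):
        out.append(f"LM={landmarks.n_landmarks}")
        for j in range(landmarks.n_landmarks):
            if landmarks.missing[s, j]:
                out.append(
                    "MISSING"
                    if missing_style == "keyword"
                    else f"{MISSING_SENTINEL[0]:g} {MISSING_SENTINEL[1]:g}"
                )
            else:
                x, y = landmarks.coords[s, j]
                out.append(f"{x:.{precision}g} {y:.{precision}g}")
        if landmarks.curves:
            out.append(f"CURVES={len(landmarks.curves)}")
            for curve in landmarks.curves:
                out.append("POINTS=" + ",".join(str(i + 1) for i in curve))
        out.append(f"ID={sid}")
    try:
        path.write_text("\n".join(out) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write TPS file {path}: {exc}") from exc


# ------------------------------------------------------------------ Newick

def read_newick(path) -> PhyloTree:
    """Read a single rooted Newick tree with branch lengths (Myr)."""
    text = Path(path).read_text().strip()
    if not text:
        raise TreeError(f"{path}: empty tree file")
    if text.count(";") > 1:
        raise TreeError(f"{path}: expected one tree per file")
    tree = PhyloTree.from_newick(text)
    tree.tip_labels = [normalize_label(t) for t in tree.tip_labels]
    for tip, lab in zip(tree.tips, tree.tip_labels):
        tip.label = lab
    return tree


def write_newick(tree: PhyloTree, path, precision: int = 10) -> None:
    Path(path).write_text(tree.to_newick(precision) + "\n")


# ---------------------------------------------------------- strategy table

def read_strategy_table(path, tree: PhyloTree | None = None) -> StrategyTable:
    """Read a two-column delimited taxon → strategy table (header optional)."""
    path = Path(path)
    if not path.read_text().strip():
        raise FormatError(f"{path}: empty strategy table")
    try:
        df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty strategy table") from None
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (taxon, strategy)")
    df = df.iloc[:, :2]
    first = [str(v).strip().lower() for v in df.iloc[0]]
    if first[0] in {"taxon", "species", "tip"} or first[1] in {"strategy", "regime", "tps"}:
        df = df.iloc[1:]
    if df.empty:
        raise FormatError(f"{path}: no data rows in strategy table")
    table = StrategyTable({str(r[0]): str(r[1]) for r in df.itertuples(index=False)})
    if tree is not None:
        extra = table.validate_against(tree)
        if extra:
            import warnings

            warnings.warn(f"strategy table lists taxa absent from the tree: {extra}")
    return table


def write_strategy_table(table: StrategyTable, path) -> None:
    df = pd.DataFrame(
        sorted(table.mapping.items()), columns=["taxon", "strategy"]
    )
    df.to_csv(path, index=False)


def check_taxon_join(
    landmarks: LandmarkSet, tree: PhyloTree, table: StrategyTable | None = None
) -> None:
    """Verify that taxon names join across all inputs; raise with an explicit diff."""
    lm = {normalize_label(x) for x in landmarks.specimen_ids}
    tp = set(tree.tip_labels)
    problems = []
    if lm != tp:
        problems.append(
            f"landmarks-only: {sorted(lm - tp)}; tree-only: {sorted(tp - lm)}"
        )
    if table is not None:
        st = set(table.mapping)
        if not tp <= st:
            problems.append(f"tips without strategy: {sorted(tp - st)}")
    if problems:
        raise FormatError("taxon sets do not join: " + " | ".join(problems))
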