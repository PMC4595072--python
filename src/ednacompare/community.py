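"""Sample-by-OTU community matrices and the plot/subplot sampling hierarchy.

The community matrix is the pipeline's entry point: one row per sample
(a plot, or a subplot within a plot), one column per OTU or species, and
non-negative abundances (sequence read counts for eDNA markers, individual
or stem counts for traditional surveys). Sample labels carry the sampling
hierarchy, e.g. ``Plot4-K`` = subplot K of Plot 4.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CommunityFormatError,
    EmptySampleError,
    HierarchyError,
)

#: Default sample-label pattern: ``<plot>-<subplot>`` with subplot codes A-P.
DEFAULT_LABEL_PATTERN = r"^(?P<plot>.+)-(?P<subplot>[A-P])$"

#: Default read-label pattern: sample id up to the first underscore.
DEFAULT_READ_PATTERN = r"^(?P<sample>[^_]+)_"


def _parse_hierarchy(
    sample_ids: Sequence[str], label_pattern: str | None
) -> tuple[dict[str, str], dict[str, str | None]]:
    """Map each sample id to (plot, subplot) under ``label_pattern``.

    ``label_pattern=None`` declares a plot-level matrix: every sample is
    its own plot with no subplot code.
    """
    plot_of: dict[str, str] = {}
    subplot_of: dict[str, str | None] = {}
    if label_pattern is None:
        for s in sample_ids:
            plot_of[s] = s
            subplot_of[s] = None
        return plot_of, subplot_of
    rx = re.compile(label_pattern)
    bad = []
    for s in sample_ids:
        m = rx.match(s)
        if m is None:
            bad.append(s)
            continue
        plot_of[s] = m.group("plot")
        subplot_of[s] = m.groupdict().get("subplot")
    if bad:
        raise HierarchyError(
            f"sample ids not matching pattern {label_pattern!r}: {bad}"
        )
    return plot_of, subplot_of


@dataclass
class CommunityMatrix:
    """Non-negative sample-by-OTU abundance table with a sampling hierarchy.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with OTU ids as columns. Cells are
        non-negative reals (read counts or individual counts).
    marker:
        Method label, e.g. ``"16S"``, ``"COI-spun"``, ``"seedlings"``.
    plot_of:
        Map sample id -> plot id. Defaults to identity (plot-level matrix).
    subplot_of:
        Map sample id -> subplot code (or None at plot level).
    """

    data: pd.DataFrame
    marker: str = "community"
    plot_of: dict[str, str] = field(default_factory=dict)
    subplot_of: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise CommunityFormatError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise CommunityFormatError("duplicate OTU ids")
        if self.data.shape[1] == 0:
            raise CommunityFormatError("matrix has no OTU columns")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise CommunityFormatError("non-finite cell values")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise CommunityFormatError(
                f"negative count at sample {self.data.index[r]!r}, "
                f"OTU {self.data.columns[c]!r}"
            )
        row_sums = values.sum(axis=1)
        if (row_sums <= 0).any():
            empty = list(self.data.index[row_sums <= 0])
            raise EmptySampleError(f"samples with zero total count: {empty}")
        if not self.plot_of:
            self.plot_of = {s: s for s in self.data.index}
            self.subplot_of = {s: None for s in self.data.index}
        missing = [s for s in self.data.index if s not in self.plot_of]
        if missing:
            raise HierarchyError(f"samples without a plot assignment: {missing}")

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def plots(self) -> list[str]:
        """Plot ids in order of first appearance among samples."""
        seen: dict[str, None] = {}
        for s in self.data.index:
            seen.setdefault(self.plot_of[s], None)
        return list(seen)

    def is_plot_level(self) -> bool:
        return all(self.plot_of[s] == s for s in self.data.index)

    def relative_abundances(self) -> np.ndarray:
        """Row-normalized composition p_ij (each row sums to 1)."""
        x = self.counts
        return x / x.sum(axis=1, keepdims=True)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CommunityMatrix":
        keep = list(sample_ids)
        return CommunityMatrix(
            data=self.data.loc[keep],
            marker=self.marker,
            plot_of={s: self.plot_of[s] for s in keep},
            subplot_of={s: self.subplot_of[s] for s in keep},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityMatrix):
            return NotImplemented
        return (
            self.marker == other.marker
            and self.data.equals(other.data)
            and self.plot_of == other.plot_of
            and self.subplot_of == other.subplot_of
        )


@dataclass
class OtuReadMap:
    """Records of (read_label, otu_id) from an OTU clustering run.

    Read labels embed the sample of origin (plot and subplot were written
    into sequence labels during deconvolution); ``read_pattern`` extracts
    the sample id, ``label_pattern`` then resolves plot/subplot.
    """

    records: list[tuple[str, str]]
    read_pattern: str = DEFAULT_READ_PATTERN
    label_pattern: str | None = DEFAULT_LABEL_PATTERN

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        read_pattern: str = DEFAULT_READ_PATTERN,
        label_pattern: str | None = DEFAULT_LABEL_PATTERN,
    ) -> "OtuReadMap":
        """Read a 2-column TSV of (read_label, otu_id)."""
        records = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise CommunityFormatError(
                        f"{path}: line {lineno} does not have 2 tab-separated fields"
                    )
                records.append((parts[0], parts[1]))
        return cls(records, read_pattern=read_pattern, label_pattern=label_pattern)


def read_community_matrix(
    path: str | Path,
    label_pattern: str | None = None,
    marker: str | None = None,
) -> CommunityMatrix:
    """Read a community matrix CSV (header = OTU ids, first column = sample ids).

    ``label_pattern`` parses the sampling hierarchy from sample ids; pass
    :data:`DEFAULT_LABEL_PATTERN` for ``Plot4-K``-style subplot labels or
    ``None`` for a plot-level matrix.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = df.index[bad.isna().to_numpy().nonzero()[0][0]]
            raise CommunityFormatError(
                f"{path}: non-numeric cell at sample {row!r}, OTU {col!r}"
            )
        df[col] = bad
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise CommunityFormatError(
            f"{path}: negative cell at sample {df.index[r]!r}, OTU {df.columns[c]!r}"
        )
    df = df.astype(float)  # counts are stored as reals regardless of source
    plot_of, subplot_of = _parse_hierarchy(list(df.index), label_pattern)
    return CommunityMatrix(
        data=df,
        marker=marker if marker is not None else path.stem,
        plot_of=plot_of,
        subplot_of=subplot_of,
    )


def write_community_matrix(cm: CommunityMatrix, path: str | Path) -> Path:
    """Write ``cm`` as CSV: UTF-8, comma-separated, first column ``sample_id``.

    Integral counts are written without a decimal point so integer matrices
    round-trip bit-exactly.
    """
    path = Path(path)
    df = cm.data
    values = df.to_numpy(dtype=float)
    all_int = np.all(values == np.floor(values))
    out = df.astype(int) if all_int else df
    out = out.copy()
    out.index.name = "sample_id"
    out.to_csv(path, encoding="utf-8")
    return path


def build_matrix_from_otu_map(otu_map: OtuReadMap, marker: str = "community") -> CommunityMatrix:
    """Tally an OTU-to-read mapping into a community matrix.

    ``counts[s][o]`` is the number of reads assigned to OTU ``o`` whose
    label resolves to sample ``s``; the grand total equals the number of
    records in the map.
    """
    if not otu_map.records:
        raise CommunityFormatError("empty OTU-read map")
    rx = re.compile(otu_map.read_pattern)
    counts: dict[tuple[str, str], int] = {}
    samples: dict[str, None] = {}
    otus: dict[str, None] = {}
    bad = []
    for read_label, otu in otu_map.records:
        m = rx.match(read_label)
        if m is None:
            bad.append(read_label)
            continue
        s = m.group("sample")
        samples.setdefault(s, None)
        otus.setdefault(otu, None)
        counts[(s, otu)] = counts.get((s, otu), 0) + 1
    if bad:
        raise HierarchyError(f"read labels mapping to no sample: {bad[:10]}")
    df = pd.DataFrame(
        0, index=pd.Index(list(samples), name="sample_id"), columns=list(otus), dtype=float
    )
    for (s, o), n in counts.items():
        df.loc[s, o] = n
    plot_of, subplot_of = _parse_hierarchy(list(df.index), otu_map.label_pattern)
    return CommunityMatrix(data=df, marker=marker, plot_of=plot_of, subplot_of=subplot_of)


def remove_singleton_otus(cm: CommunityMatrix) -> CommunityMatrix:
    """Drop OTUs with a grand-total count of exactly 1 (single-read OTUs).

    Mirrors the alternative matrix set in which all single-read OTUs are
    removed as likely sequencing artifacts. Raises
    :class:`EmptySampleError` if a sample would lose all its reads.
    """
    totals = cm.data.sum(axis=0)
    keep = totals[totals != 1].index
    if len(keep) == 0:
        raise EmptySampleError("all OTUs are singletons; matrix would be empty")
    data = cm.data[keep]
    row_sums = data.sum(axis=1)
    if (row_sums <= 0).any():
        empty = list(data.index[row_sums <= 0])
        raise EmptySampleError(
            f"singleton removal emptied samples: {empty}"
        )
    return CommunityMatrix(
        data=data,
        marker=cm.marker,
        plot_of=dict(cm.plot_of),
        subplot_of=dict(cm.subplot_of),
    )


def pool_to_plots(cm: CommunityMatrix) -> CommunityMatrix:
    """Sum subplot rows into one row per plot.

    Plot rows keep the order of first appearance; the result is plot-level
    (each sample is its own plot). Grand totals and per-OTU totals are
    conserved.
    """
    plots = cm.plots
    groups = pd.Series({s: cm.plot_of[s] for s in cm.sample_ids})
    pooled = cm.data.groupby(groups, sort=False).sum()
    pooled = pooled.loc[plots]
    return CommunityMatrix(
        data=pooled,
        marker=cm.marker,
        plot_of={p: p for p in plots},
        subplot_of={p: None for p in plots},
    )


def to_presence_absence(cm: CommunityMatrix, mode: str = "binary") -> CommunityMatrix:
    """Convert counts to occurrences.

    ``mode="binary"``: cells become 0/1 at the same sample level.
    ``mode="subplot-frequency"``: pools to plot level, each cell the
    number of subplots in which the OTU occurs (the 1-24 subplot-presence
    scores used for plant surveys on 24-subplot plots).
    """
    if mode == "binary":
        data = (cm.data > 0).astype(float)
        return CommunityMatrix(
            data=data,
            marker=cm.marker,
            plot_of=dict(cm.plot_of),
            subplot_of=dict(cm.subplot_of),
        )
    if mode == "subplot-frequency":
        n_subplots = pd.Series({s: cm.plot_of[s] for s in cm.sample_ids}).value_counts()
        if (n_subplots > 24).any():
            bad = list(n_subplots[n_subplots > 24].index)
            raise HierarchyError(
                f"plots with more than 24 subplots: {bad}"
            )
        binary = to_presence_absence(cm, mode="binary")
        return pool_to_plots(binary)
    raise ValueError(f"unknown mode {mode!r}; use 'binary' or 'subplot-frequency'")
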