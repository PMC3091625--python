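"""Readers and writers for bead-summary expression data.

The on-disk dialect mirrors the structure of a BeadStudio "Sample Probe
Profile" export: one header row, a leading ``ProbeID`` column, and one block
of columns per sample named ``<sample>.AVG_Signal``, ``<sample>.BEAD_STDERR``,
``<sample>.Avg_NBEADS`` and ``<sample>.Detection Pval``.  Everything is plain
tab-separated text with a fixed decimal point, so files stay diffable and
locale-independent.

Negative intensities are legal throughout: BeadStudio-style background
subtraction routinely produces them, and positivity is only enforced by the
transforms that require it (see :mod:`beadnorm.normalize`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProbeProfileTable",
    "ControlProfile",
    "SampleDesign",
    "ReferenceFoldChanges",
    "BeadFormatError",
    "read_sample_probe_profile",
    "write_sample_probe_profile",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_design",
    "write_design",
    "read_reference_fold_changes",
    "write_reference_fold_changes",
]

#: Number of significant digits guaranteed to survive a write/read cycle.
ROUNDTRIP_DIGITS = 6

_PROFILE_FIELDS = ("AVG_Signal", "BEAD_STDERR", "Avg_NBEADS", "Detection Pval")


class BeadFormatError(ValueError):
    """Raised when an on-disk file violates the expected dialect."""


@dataclass
class ProbeProfileTable:
    """Probe x sample bead-summary intensities with per-probe bead statistics.

    All matrices are pandas DataFrames indexed by probe id with one column per
    sample.  ``detection_p`` is optional; readers leave it ``None`` when the
    corresponding columns are absent.
    """

    avg_signal: pd.DataFrame
    bead_stderr: pd.DataFrame | None = None
    n_beads: pd.DataFrame | None = None
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx, cols = self.avg_signal.index, self.avg_signal.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise BeadFormatError(f"duplicate probe ids: {dupes}")
        for name in ("bead_stderr", "n_beads", "detection_p"):
            m = getattr(self, name)
            if m is None:
                continue
            if m.shape != self.avg_signal.shape:
                raise BeadFormatError(
                    f"{name} shape {m.shape} does not match avg_signal {self.avg_signal.shape}"
                )
            if not (m.index.equals(idx) and m.columns.equals(cols)):
                raise BeadFormatError(f"{name} labels do not match avg_signal")
        if self.n_beads is not None and len(idx) and (self.n_beads.values < 1).any():
            raise BeadFormatError("n_beads must be >= 1")
        if self.bead_stderr is not None and len(idx) and (self.bead_stderr.values < 0).any():
            raise BeadFormatError("bead_stderr must be >= 0")
        if self.detection_p is not None and len(idx):
            dp = self.detection_p.values
            if ((dp < 0) | (dp > 1)).any():
                raise BeadFormatError("detection_p must lie in [0, 1]")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.avg_signal.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.avg_signal.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.avg_signal.shape

    def equals(self, other: "ProbeProfileTable", rtol: float = 1e-5) -> bool:
        """Field-by-field equality within relative tolerance."""
        for name in ("avg_signal", "bead_stderr", "n_beads", "detection_p"):
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                return False
            if a is None:
                continue
            if not (a.index.equals(b.index) and a.columns.equals(b.columns)):
                return False
            if not np.allclose(a.values, b.values, rtol=rtol, atol=0, equal_nan=True):
                return False
        return True


@dataclass
class ControlProfile:
    """Negative-control x sample raw intensities."""

    avg_signal: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.avg_signal.values).all():
            raise BeadFormatError("control intensities must be finite")

    @property
    def control_ids(self) -> list[str]:
        return list(self.avg_signal.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.avg_signal.columns)


@dataclass
class SampleDesign:
    """Sample-to-group assignment for a one-way layout.

    ``table`` has columns ``sample_id``, ``group`` and ``replicate``; extra
    columns are carried along untouched as annotations.
    """

    table: pd.DataFrame
    singleton_groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise BeadFormatError(f"design table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dupes = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise BeadFormatError(f"duplicate sample ids in design: {dupes.tolist()}")
        sizes = self.table.groupby("group", sort=False).size()
        self.singleton_groups = sizes.index[sizes < 2].tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def samples_in(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "sample_id"].tolist()

    def check_samples(self, sample_ids) -> None:
        """Every profiled sample must appear exactly once in the design."""
        missing = [s for s in sample_ids if s not in set(self.sample_ids)]
        if missing:
            raise BeadFormatError(f"samples missing from design: {missing}")


@dataclass
class ReferenceFoldChanges:
    """Reference (qRT-PCR-like) log2 fold changes per gene and comparison.

    ``table`` columns: ``gene_id``, ``comparison`` (string "<test>_vs_<ref>")
    and ``log2_ratio``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "comparison", "log2_ratio"}
        missing = required - set(self.table.columns)
        if missing:
            raise BeadFormatError(f"reference table missing columns: {sorted(missing)}")
        if not np.isfinite(self.table["log2_ratio"].to_numpy(float)).all():
            raise BeadFormatError("reference log2 ratios must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["gene_id"]))

    @property
    def comparisons(self) -> list[str]:
        return list(dict.fromkeys(self.table["comparison"]))

    def lookup(self, gene_id: str, comparison: str) -> float:
        sel = self.table[
            (self.table["gene_id"] == gene_id) & (self.table["comparison"] == comparison)
        ]
        if sel.empty:
            raise KeyError(f"no reference ratio for {gene_id} / {comparison}")
        return float(sel["log2_ratio"].iloc[0])


# ---------------------------------------------------------------------------
# Sample Probe Profile dialect
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.{ROUNDTRIP_DIGITS}g}"


def write_sample_probe_profile(table: ProbeProfileTable, path) -> None:
    """Write ``table`` in the Sample Probe Profile dialect.

    Optional matrices that are absent are simply omitted from the header.
    """
    blocks: list[tuple[str, pd.DataFrame]] = [("AVG_Signal", table.avg_signal)]
    for name, attr in (
        ("BEAD_STDERR", table.bead_stderr),
        ("Avg_NBEADS", table.n_beads),
        ("Detection Pval", table.detection_p),
    ):
        if attr is not None:
            blocks.append((name, attr))
    samples = table.sample_ids
    header = ["ProbeID"] + [f"{s}.{b}" for s in samples for b, _ in blocks]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for probe in table.probe_ids:
            row = [str(probe)]
            for s in samples:
                for bname, mat in blocks:
                    v = mat.at[probe, s]
                    row.append(str(int(v)) if bname == "Avg_NBEADS" else _fmt(float(v)))
            fh.write("\t".join(row) + "\n")


def read_sample_probe_profile(path) -> ProbeProfileTable:
    """Read a Sample Probe Profile file into a :class:`ProbeProfileTable`."""
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise BeadFormatError(f"{path}: empty file")
        header = header_line.split("\t")
        if header[0] not in ("ProbeID", "TargetID"):
            raise BeadFormatError(
                f"{path}: first column must be ProbeID/TargetID, got {header[0]!r}"
            )
        # parse "<sample>.<field>" columns, preserving sample order
        columns: list[tuple[str, str]] = []
        for col in header[1:]:
            sample, dot, fieldname = col.rpartition(".")
            if not dot or fieldname not in _PROFILE_FIELDS:
                raise BeadFormatError(
                    f"{path}: malformed profile column {col!r} "
                    f"(expected '<sample>.<one of {_PROFILE_FIELDS}>')"
                )
            columns.append((sample, fieldname))
        samples = list(dict.fromkeys(s for s, _ in columns))
        fields_present = list(dict.fromkeys(f for _, f in columns))
        for s in samples:
            have = [f for smp, f in columns if smp == s]
            if have != fields_present:
                raise BeadFormatError(
                    f"{path}: sample {s!r} has column block {have}, expected {fields_present}"
                )

        probes: list[str] = []
        data: dict[str, list[list[float]]] = {f: [] for f in fields_present}
        ncol = len(header)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != ncol:
                raise BeadFormatError(
                    f"{path}:{lineno}: expected {ncol} fields, got {len(parts)}"
                )
            probes.append(parts[0])
            row: dict[str, list[float]] = {f: [] for f in fields_present}
            for (sample, fieldname), cell in zip(columns, parts[1:]):
                try:
                    row[fieldname].append(float(cell))
                except ValueError as exc:
                    raise BeadFormatError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in "
                        f"{sample}.{fieldname}"
                    ) from exc
            for f in fields_present:
                data[f].append(row[f])

    def _df(fieldname: str) -> pd.DataFrame | None:
        if fieldname not in fields_present:
            return None
        return pd.DataFrame(data[fieldname], index=probes, columns=samples, dtype=float)

    if "AVG_Signal" not in fields_present:
        raise BeadFormatError(f"{path}: no AVG_Signal columns found")
    nb = _df("Avg_NBEADS")
    if nb is not None:
        nb = nb.round().astype(int)
    return ProbeProfileTable(
        avg_signal=_df("AVG_Signal"),
        bead_stderr=_df("BEAD_STDERR"),
        n_beads=nb,
        detection_p=_df("Detection Pval"),
    )


# ---------------------------------------------------------------------------
# Plain matrix TSV
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    """Write a labelled probe x sample matrix as plain TSV."""
    out = matrix.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format=f"%.{ROUNDTRIP_DIGITS}g")


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a probe x sample matrix TSV written by :func:`write_matrix_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise BeadFormatError(f"{path}: non-numeric matrix cell ({exc})") from exc
    df.index = df.index.astype(str)
    df.index.name = None
    return df


# ---------------------------------------------------------------------------
# Design and reference tables
# ---------------------------------------------------------------------------

def read_design(path, profile_samples=None) -> SampleDesign:
    """Read a sample design TSV (columns sample_id, group, replicate).

    If ``profile_samples`` is given, checks that every profiled sample appears
    in the design.  Unknown extra columns are preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    design = SampleDesign(df)
    if profile_samples is not None:
        design.check_samples(profile_samples)
    return design


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_reference_fold_changes(path) -> ReferenceFoldChanges:
    """Read a reference fold-change TSV (gene_id, comparison, log2_ratio)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "comparison": str})
    return ReferenceFoldChanges(df)


def write_reference_fold_changes(ref: ReferenceFoldChanges, path) -> None:
    ref.table.to_csv(path, sep="\t", index=False, float_format=f"%.{ROUNDTRIP_DIGITS}g")
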