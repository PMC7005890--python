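"""Reading and writing nCounter lane files (RCC dialect) and count tables.

The nCounter platform emits one plain-text RCC file per sample lane, with
``<Tag>``...``</Tag>`` delimited sections; the ``Code_Summary`` section holds
one ``CodeClass,Name,Accession,Count`` row per probe.  This module parses
those lanes into :class:`SampleRecord` objects, assembles records into a
:class:`CountMatrix` (the pipeline's universal currency: an integer
probe x sample grid with probe-class annotations and sample metadata), and
round-trips count tables and sample sheets as TSV/CSV.

Counts are hard integers: nCounter output is a digital molecule count, so
fractional values are rejected rather than rounded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, IntegrityError

CODE_CLASSES = ("Endogenous", "Negative", "Positive", "SpikeIn", "Housekeeping")

#: Case-insensitive aliases for probe code classes as they appear in RCC
#: files from different panel releases.  "Ligation" probes are the negative
#: ligation controls of the miRNA codeset and estimate background.
CLASS_ALIASES: Mapping[str, str] = {
    "endogenous": "Endogenous",
    "endogenous1": "Endogenous",
    "negative": "Negative",
    "ligation": "Negative",
    "positive": "Positive",
    "spikein": "SpikeIn",
    "spike-in": "SpikeIn",
    "spike_in": "SpikeIn",
    "spike": "SpikeIn",
    "housekeeping": "Housekeeping",
}

GROUPS = ("case", "control")
FRACTIONS = ("cell_fraction", "ev_fraction")


def normalize_code_class(raw: str) -> str:
    """Map a raw CodeClass string onto the five-value enum.

    Raises ``ValueError`` for classes outside the alias table.
    """
    key = raw.strip().lower()
    if key not in CLASS_ALIASES:
        raise ValueError(f"unknown probe code class: {raw!r}")
    return CLASS_ALIASES[key]


def _parse_count(raw: str, probe: str) -> int:
    value = raw.strip()
    try:
        as_float = float(value)
    except ValueError as exc:
        raise ValueError(f"non-numeric count {value!r} for probe {probe!r}") from exc
    if not float(as_float).is_integer():
        raise ValueError(f"non-integer count {value!r} for probe {probe!r}")
    count = int(as_float)
    if count < 0:
        raise ValueError(f"negative count {count} for probe {probe!r}")
    return count


@dataclass(frozen=True)
class ProbeAnnotation:
    """One panel probe: unique id, code class and free-text accession."""

    probe_id: str
    code_class: str
    accession: str = ""

    def __post_init__(self) -> None:
        if self.code_class not in CODE_CLASSES:
            raise ValueError(f"invalid code class {self.code_class!r}")


@dataclass
class SampleRecord:
    """One lane: sample id, optional group/fraction/RIN metadata and counts."""

    sample_id: str
    counts: dict[str, int]
    annotations: list[ProbeAnnotation] = field(default_factory=list)
    group: str | None = None
    fraction: str | None = None
    rin: float | None = None

    def __post_init__(self) -> None:
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"invalid group {self.group!r}")
        if self.fraction is not None and self.fraction not in FRACTIONS:
            raise ValueError(f"invalid fraction {self.fraction!r}")
        for probe, count in self.counts.items():
            if count < 0 or int(count) != count:
                raise ValueError(f"invalid count {count!r} for probe {probe!r}")


@dataclass
class CountMatrix:
    """Integer probe x sample count grid with annotations and sample metadata.

    Attributes
    ----------
    counts : DataFrame
        Probes (rows, indexed by probe_id) by samples (columns, sample_id),
        dtype int64.
    annotations : DataFrame
        Indexed by probe_id, columns ``code_class`` and ``accession``; row
        order defines the canonical probe order.
    samples : DataFrame
        Indexed by sample_id, columns ``group``, ``fraction``, ``rin``;
        row order defines the canonical sample order.
    """

    counts: pd.DataFrame
    annotations: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.annotations.index.has_duplicates:
            raise IntegrityError("duplicate probe ids in annotations")
        if self.samples.index.has_duplicates:
            raise IntegrityError("duplicate sample ids in sample sheet")
        if list(self.counts.index) != list(self.annotations.index):
            raise IntegrityError("count rows do not match annotation order")
        if list(self.counts.columns) != list(self.samples.index):
            raise IntegrityError("count columns do not match sample order")
        values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            raise IntegrityError("negative counts in matrix")
        bad = set(self.annotations["code_class"]) - set(CODE_CLASSES)
        if bad:
            raise IntegrityError(f"invalid code classes: {sorted(bad)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.annotations.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def probes_of_class(self, code_class: str) -> list[str]:
        mask = self.annotations["code_class"] == code_class
        return list(self.annotations.index[mask])

    @property
    def endogenous_ids(self) -> list[str]:
        return self.probes_of_class("Endogenous")

    def subset(
        self,
        probes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "CountMatrix":
        """Return a new matrix restricted to the given probes/samples,
        preserving canonical order."""
        probes = self.probe_ids if probes is None else [p for p in self.probe_ids if p in set(probes)]
        samples = self.sample_ids if samples is None else [s for s in self.sample_ids if s in set(samples)]
        return CountMatrix(
            counts=self.counts.loc[probes, samples].copy(),
            annotations=self.annotations.loc[probes].copy(),
            samples=self.samples.loc[samples].copy(),
        )

    @classmethod
    def from_records(
        cls,
        records: Iterable[SampleRecord],
        annotations: Sequence[ProbeAnnotation] | None = None,
    ) -> "CountMatrix":
        """Assemble lane records into a matrix.

        Annotations default to the (identical) annotation lists carried by
        the records; every record must cover the full probe panel.
        """
        records = list(records)
        if not records:
            raise IntegrityError("no sample records provided")
        if annotations is None:
            annotations = records[0].annotations
            if not annotations:
                raise IntegrityError("records carry no probe annotations")
        ann = pd.DataFrame(
            {
                "code_class": [a.code_class for a in annotations],
                "accession": [a.accession for a in annotations],
            },
            index=pd.Index([a.probe_id for a in annotations], name="probe_id"),
        )
        counts = {}
        meta = {"group": [], "fraction": [], "rin": []}
        ids = []
        for rec in records:
            missing = set(ann.index) - set(rec.counts)
            extra = set(rec.counts) - set(ann.index)
            if missing or extra:
                raise IntegrityError(
                    f"sample {rec.sample_id!r} probe set mismatch "
                    f"(missing {len(missing)}, extra {len(extra)})"
                )
            counts[rec.sample_id] = [rec.counts[p] for p in ann.index]
            ids.append(rec.sample_id)
            meta["group"].append(rec.group)
            meta["fraction"].append(rec.fraction)
            meta["rin"].append(rec.rin)
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate sample ids among records")
        frame = pd.DataFrame(counts, index=ann.index, dtype="int64")
        samples = pd.DataFrame(meta, index=pd.Index(ids, name="sample_id"))
        return cls(counts=frame, annotations=ann, samples=samples)


# -- RCC lane files ---------------------------------------------------------

_REQUIRED_SECTIONS = ("Header", "Sample_Attributes", "Lane_Attributes", "Code_Summary")


def _split_sections(text: str, path: Path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for lineno, line in enumerate(text.splitlines(), 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("</") and stripped.endswith(">"):
            tag = stripped[2:-1]
            if tag != current:
                raise FormatError(f"{path}:{lineno}: closing tag {tag!r} does not match open section {current!r}")
            current = None
        elif stripped.startswith("<") and stripped.endswith(">"):
            current = stripped[1:-1]
            if current in sections:
                raise FormatError(f"{path}:{lineno}: duplicate section {current!r}")
            sections[current] = []
        elif current is not None:
            sections[current].append(stripped)
        # stray lines outside any section are ignored
    return sections


def read_rcc(path: str | Path) -> SampleRecord:
    """Parse one RCC lane file into a :class:`SampleRecord`.

    Unknown sections are skipped with a warning (forward compatibility);
    a missing ``Code_Summary`` section is a :class:`FormatError`, a
    non-integer count a ``ValueError`` and a duplicated probe name an
    :class:`IntegrityError`.
    """
    path = Path(path)
    sections = _split_sections(path.read_text(), path)
    for tag in sections:
        if tag not in _REQUIRED_SECTIONS:
            warnings.warn(f"{path}: skipping unknown RCC section {tag!r}", stacklevel=2)
    if "Code_Summary" not in sections:
        raise FormatError(f"{path}: missing Code_Summary section")

    attrs = {}
    for line in sections.get("Sample_Attributes", []):
        key, _, value = line.partition(",")
        attrs[key.strip()] = value.strip()
    sample_id = attrs.get("ID") or path.stem

    counts: dict[str, int] = {}
    annotations: list[ProbeAnnotation] = []
    rows = sections["Code_Summary"]
    if rows and rows[0].lower().startswith("codeclass"):
        rows = rows[1:]
    for row in rows:
        parts = row.split(",")
        if len(parts) != 4:
            raise FormatError(f"{path}: malformed Code_Summary row {row!r}")
        code_class, name, accession, raw_count = (p.strip() for p in parts)
        if name in counts:
            raise IntegrityError(f"{path}: duplicate probe name {name!r}")
        counts[name] = _parse_count(raw_count, name)
        annotations.append(ProbeAnnotation(name, normalize_code_class(code_class), accession))
    return SampleRecord(sample_id=sample_id, counts=counts, annotations=annotations)


def write_rcc(record: SampleRecord, path: str | Path) -> Path:
    """Write a lane record in the RCC dialect (used to emit synthetic lanes)."""
    path = Path(path)
    lines = [
        "<Header>",
        "FileVersion,1.7",
        "SoftwareVersion,mirnome",
        "</Header>",
        "<Sample_Attributes>",
        f"ID,{record.sample_id}",
        "</Sample_Attributes>",
        "<Lane_Attributes>",
        "ID,1",
        "</Lane_Attributes>",
        "<Code_Summary>",
        "CodeClass,Name,Accession,Count",
    ]
    for ann in record.annotations:
        lines.append(f"{ann.code_class},{ann.probe_id},{ann.accession},{record.counts[ann.probe_id]}")
    lines += ["</Code_Summary>", ""]
    path.write_text("\n".join(lines))
    return path


def read_rcc_dir(directory: str | Path) -> list[SampleRecord]:
    """Read every ``*.RCC`` / ``*.rcc`` lane file in a directory, sorted by name."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.rcc")) + sorted(directory.glob("*.RCC"))
    if not paths:
        raise FormatError(f"no RCC files found in {directory}")
    return [read_rcc(p) for p in paths]


# -- count tables and sample sheets ----------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_count_table(path: str | Path, sample_sheet: str | Path) -> CountMatrix:
    """Read a probe x sample count table plus its sample sheet.

    The table carries ``probe_id``, ``code_class``, ``accession`` columns then
    one integer column per sample; the sheet maps sample_id to group,
    fraction and optional RIN.  Sample order follows the sheet.
    """
    path, sheet_path = Path(path), Path(sample_sheet)
    table = pd.read_csv(path, sep=_sep_for(path), dtype=str).fillna("")
    sheet = pd.read_csv(sheet_path, sep=_sep_for(sheet_path), dtype=str)
    for col in ("probe_id", "code_class"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if "sample_id" not in sheet.columns:
        raise FormatError(f"{sheet_path}: missing column 'sample_id'")

    meta_cols = [c for c in ("probe_id", "code_class", "accession") if c in table.columns]
    table_samples = [c for c in table.columns if c not in meta_cols]
    sheet_samples = list(sheet["sample_id"])
    if set(table_samples) != set(sheet_samples):
        missing = set(table_samples) ^ set(sheet_samples)
        raise IntegrityError(f"sample sets of table and sheet differ: {sorted(missing)}")

    if table["probe_id"].duplicated().any():
        raise IntegrityError(f"{path}: duplicate probe ids")
    ann = pd.DataFrame(
        {
            "code_class": [normalize_code_class(c) for c in table["code_class"]],
            "accession": table.get("accession", pd.Series([""] * len(table))).tolist(),
        },
        index=pd.Index(table["probe_id"], name="probe_id"),
    )
    counts = pd.DataFrame(index=ann.index)
    for sid in sheet_samples:
        counts[sid] = [
            _parse_count(v, p) for v, p in zip(table[sid], table["probe_id"])
        ]
    counts = counts.astype("int64")

    def _rin(v: object) -> float | None:
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
            return None
        return float(v)

    samples = pd.DataFrame(
        {
            "group": sheet["group"].tolist() if "group" in sheet else [None] * len(sheet),
            "fraction": sheet["fraction"].tolist() if "fraction" in sheet else [None] * len(sheet),
            "rin": [_rin(v) for v in sheet["rin"]] if "rin" in sheet else [None] * len(sheet),
        },
        index=pd.Index(sheet_samples, name="sample_id"),
    )
    return CountMatrix(counts=counts, annotations=ann, samples=samples)


def write_count_table(matrix: CountMatrix, path: str | Path) -> Path:
    """Write the count grid as CSV/TSV with deterministic row/column order.

    Rows follow annotation order, columns follow sheet order; counts are
    plain integers (no exponents), so identical matrices produce identical
    bytes.
    """
    path = Path(path)
    sep = _sep_for(path)
    out = pd.DataFrame(
        {
            "probe_id": matrix.annotations.index,
            "code_class": matrix.annotations["code_class"].to_numpy(),
            "accession": matrix.annotations["accession"].to_numpy(),
        }
    )
    for sid in matrix.sample_ids:
        out[sid] = matrix.counts[sid].to_numpy()
    out.to_csv(path, sep=sep, index=False, lineterminator="\n")
    return path


def write_sample_sheet(matrix: CountMatrix, path: str | Path) -> Path:
    """Write the sample metadata (sample_id, group, fraction, rin) as CSV/TSV."""
    path = Path(path)
    sheet = matrix.samples.reset_index()
    sheet["rin"] = ["" if v is None else v for v in sheet["rin"]]
    sheet.to_csv(path, sep=_sep_for(path), index=False, lineterminator="\n")
    return path
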