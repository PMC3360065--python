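"""Reading, writing and normalising siRNA efficacy tables.

Conventions enforced here and relied on by every downstream module:

* sequences are 19-nt **antisense** (guide) strands, written 5'→3', over the
  RNA alphabet ``{A, C, G, U}``.  DNA-encoded deposits (``T``) are silently
  mapped to ``U``; tables whose sequences were recorded on the sense strand
  are converted by RNA reverse complement.
* efficacy is the remaining mRNA/protein **product level** in ``[0, 1]``.
  Lower means more potent silencing — a feature *negatively* correlated with
  product level *increases* potency.  All statistics in
  :mod:`sirnarank.stats_validation` follow this sign convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SIRNA_LENGTH = 19

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")

Orientation = Literal["antisense", "sense"]


class DatasetError(Exception):
    """Base class for dataset-level failures."""


class InvalidSequenceError(DatasetError):
    """A sequence contains a non-ACGUT character or has the wrong length.

    ``position`` is the 1-based offset of the first offending character, or
    ``None`` for a length violation.
    """

    def __init__(self, sequence: str, message: str, position: int | None = None):
        self.sequence = sequence
        self.position = position
        super().__init__(message)


class EmptyDatasetError(DatasetError):
    """No valid record survived loading."""


class ConfigurationError(DatasetError):
    """The column configuration does not match the file."""


@dataclass(frozen=True)
class SiRNARecord:
    """One 19-nt antisense siRNA with its measured product level.

    Attributes
    ----------
    sequence:
        Normalised antisense strand, 5'→3', over {A, C, G, U}.
    efficacy:
        Product level in [0, 1]; lower = more potent.
    task_id:
        1-based platform/dataset index.
    source_label:
        Free-text provenance.
    """

    sequence: str
    efficacy: float
    task_id: int = 1
    source_label: str = ""

    def __post_init__(self):
        if len(self.sequence) != SIRNA_LENGTH:
            raise InvalidSequenceError(
                self.sequence,
                f"expected {SIRNA_LENGTH}-nt sequence, got {len(self.sequence)}",
            )
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in "ACGU":
                raise InvalidSequenceError(
                    self.sequence,
                    f"invalid character {ch!r} at position {pos}",
                    position=pos,
                )
        if not 0.0 <= self.efficacy <= 1.0:
            raise DatasetError(f"efficacy {self.efficacy} outside [0, 1]")


@dataclass
class TaskDataset:
    """All records of a single platform (one regression task)."""

    records: list[SiRNARecord]

    def __post_init__(self):
        if not self.records:
            raise EmptyDatasetError("a task needs at least one record")
        ids = {r.task_id for r in self.records}
        if len(ids) != 1:
            raise DatasetError(f"records span multiple task ids: {sorted(ids)}")

    @property
    def task_id(self) -> int:
        return self.records[0].task_id

    @property
    def size(self) -> int:
        return len(self.records)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def efficacies(self) -> list[float]:
        return [r.efficacy for r in self.records]


@dataclass(frozen=True)
class ManifestEntry:
    task_id: int
    name: str
    size: int
    concentration: str = ""
    recorded_orientation: Orientation = "antisense"


@dataclass
class DatasetManifest:
    """Ordered catalogue of the platforms making up a meta-collection."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self):
        ids = [e.task_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise DatasetError("duplicate task ids in manifest")
        if any(e.size <= 0 for e in self.entries):
            raise DatasetError("manifest sizes must be positive")

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])


#: The published ten-platform siRNA efficacy meta-collection: heterogeneous
#: sources (different cell lines, assays, delivery methods and siRNA
#: concentrations) sharing one sequence/efficacy format.  Two platforms
#: deposited sense-strand sequences.
DEFAULT_MANIFEST = DatasetManifest(
    [
        ManifestEntry(1, "Novartis (Huesken 2005)", 2431, "50 nM", "antisense"),
        ManifestEntry(2, "Jagla 2005", 601, "100 nM", "antisense"),
        ManifestEntry(3, "Katoh & Suzuki 2007", 702, "10/25 nM", "sense"),
        ManifestEntry(4, "Amgen-Dharmacon (Reynolds 2004)", 239, "100 nM", "antisense"),
        ManifestEntry(5, "Harborth 2003", 42, "100 nM", "antisense"),
        ManifestEntry(6, "Hsieh 2004", 108, "100 nM", "antisense"),
        ManifestEntry(7, "Khvorova 2003", 10, "100 nM", "antisense"),
        ManifestEntry(8, "Vickers 2003", 76, "100 nM", "antisense"),
        ManifestEntry(9, "Ui-Tei 2004", 50, "50 nM", "antisense"),
        ManifestEntry(10, "Amarzguioui & Prydz 2004", 223, "25 nM", "sense"),
    ]
)


def manifest_total(manifest: DatasetManifest) -> int:
    """Total record count across all platforms of a manifest."""
    if not manifest.entries:
        raise DatasetError("empty manifest")
    return sum(e.size for e in manifest.entries)


def reverse_complement(seq: str) -> str:
    """RNA reverse complement (A↔U, C↔G), read back 5'→3'."""
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def to_antisense(
    seq: str,
    recorded_orientation: Orientation = "antisense",
    *,
    expected_length: int | None = SIRNA_LENGTH,
) -> str:
    """Normalise a deposited sequence to the antisense strand.

    ``T`` is tolerated on input and mapped to ``U``; any other non-ACGU
    character raises :class:`InvalidSequenceError` naming the 1-based
    position.  Sense-recorded sequences are reverse-complemented.

    ``expected_length=None`` disables the length check (unit-test harness
    hook); the library default enforces 19 nt.
    """
    norm = seq.strip().upper().replace("T", "U")
    if expected_length is not None and len(norm) != expected_length:
        raise InvalidSequenceError(
            seq, f"expected {expected_length}-nt sequence, got {len(norm)}"
        )
    for pos, ch in enumerate(norm, start=1):
        if ch not in "ACGU":
            raise InvalidSequenceError(
                seq, f"invalid character {ch!r} at position {pos}", position=pos
            )
    if recorded_orientation == "sense":
        return reverse_complement(norm)
    if recorded_orientation != "antisense":
        raise ValueError(f"unknown orientation {recorded_orientation!r}")
    return norm


def normalize_efficacy(
    values: Sequence[float], mode: Literal["clip", "minmax", "none"] = "clip"
) -> list[float]:
    """Map raw efficacy values into [0, 1].

    ``clip`` clamps (the default: cross-platform rescaling is deliberately
    *not* applied, the joint model handles heterogeneity); ``minmax``
    rescales to span [0, 1]; ``none`` passes through but verifies the range.
    """
    vals = [float(v) for v in values]
    if any(not _finite(v) for v in vals):
        raise DatasetError("efficacy values must be finite")
    if mode == "clip":
        return [min(1.0, max(0.0, v)) for v in vals]
    if mode == "minmax":
        lo, hi = min(vals), max(vals)
        if hi == lo:
            raise DatasetError("minmax normalisation undefined for constant values")
        return [(v - lo) / (hi - lo) for v in vals]
    if mode == "none":
        if any(v < 0.0 or v > 1.0 for v in vals):
            raise DatasetError("values outside [0, 1] with normalisation 'none'")
        return vals
    raise ValueError(f"unknown normalisation mode {mode!r}")


def _finite(v: float) -> bool:
    return v == v and abs(v) != float("inf")


@dataclass(frozen=True)
class ColumnConfig:
    """Maps table columns to record fields (names or 0-based positions)."""

    sequence: str | int = "sequence"
    efficacy: str | int = "efficacy"
    orientation: Orientation = "antisense"
    normalization: Literal["clip", "minmax", "none"] = "clip"
    delimiter: str | None = None  # None → sniff \t vs ,


def load_dataset_table(
    path: str | Path,
    column_config: ColumnConfig | None = None,
    *,
    task_id: int = 1,
    source_label: str | None = None,
) -> TaskDataset:
    """Load one delimited efficacy table into a :class:`TaskDataset`.

    Malformed rows (bad length, bad alphabet) are skipped with a logged
    warning and counted; a file yielding zero valid rows raises
    :class:`EmptyDatasetError`.
    """
    cfg = column_config or ColumnConfig()
    path = Path(path)
    delim = cfg.delimiter
    if delim is None:
        head = path.open().readline()
        delim = "\t" if "\t" in head else ","
    positional = isinstance(cfg.sequence, int)
    df = pd.read_csv(path, sep=delim, header=None if positional else 0, dtype=str)
    for col in (cfg.sequence, cfg.efficacy):
        if (positional and col >= df.shape[1]) or (not positional and col not in df.columns):
            raise ConfigurationError(f"column {col!r} not found in {path.name}")

    raw_seq = df[cfg.sequence].tolist()
    try:
        raw_eff = [float(v) for v in df[cfg.efficacy]]
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"non-numeric efficacy column in {path.name}: {exc}")
    eff = normalize_efficacy(raw_eff, cfg.normalization)

    label = source_label if source_label is not None else path.stem
    records: list[SiRNARecord] = []
    skipped = 0
    for seq, e in zip(raw_seq, eff):
        try:
            anti = to_antisense(seq, cfg.orientation)
            records.append(SiRNARecord(anti, e, task_id=task_id, source_label=label))
        except DatasetError as exc:
            skipped += 1
            logger.warning("skipping record %r: %s", seq, exc)
    if not records:
        raise EmptyDatasetError(f"no valid records in {path}")
    if skipped:
        logger.warning("%s: skipped %d malformed record(s)", path.name, skipped)
    return TaskDataset(records)


def write_dataset_table(dataset: TaskDataset, path: str | Path) -> None:
    """Write a task back out as TSV (sequence, efficacy, task_id, source)."""
    df = pd.DataFrame(
        {
            "sequence": dataset.sequences(),
            "efficacy": [f"{e:.6f}" for e in dataset.efficacies()],
            "task_id": [r.task_id for r in dataset.records],
            "source_label": [r.source_label for r in dataset.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def build_manifest(datasets: Iterable[TaskDataset], names: dict[int, str] | None = None) -> DatasetManifest:
    """Summarise loaded tasks into a manifest (sizes from the data)."""
    names = names or {}
    entries = [
        ManifestEntry(d.task_id, names.get(d.task_id, f"task {d.task_id}"), d.size)
        for d in datasets
    ]
    return DatasetManifest(entries)
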