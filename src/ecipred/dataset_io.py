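"""Dataset data model and on-disk format.

An activity dataset couples an enzyme family (amino-acid sequences) with a
chemical library (SMILES) through an enzymes x chemicals activity matrix.
Cells may be missing (un-assayed pairs); missing cells are never imputed and
are excluded from every downstream statistic, training pair and metric.

On disk a dataset is a directory of four plain-text files::

    enzymes.fasta    standard FASTA, id = first whitespace-delimited token
    chemicals.csv    header: chemical_id,smiles   (smiles may be empty)
    activity.csv     row ids = enzyme ids, column ids = chemical ids;
                     "" or "NA" denotes a missing cell
    metadata.yaml    keys: name, substrate_library, activity_threshold,
                     activity_scale

The CSV dialect is fixed (comma-separated, UTF-8) so that save -> load is a
bit-exact round trip on identifiers and accurate to float repr on values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import (
    ConsistencyError,
    DatasetLoadError,
    DomainError,
    ValidationError,
)

#: The 20 canonical amino acids, alphabetical by one-letter code.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted in input sequences. X marks an ambiguous residue and is
#: ignored by composition descriptors; any other letter is rejected.
VALID_RESIDUES = frozenset(AA_ALPHABET) | {"X"}

SUBSTRATE_LIBRARIES = ("industrial", "physiological")
ACTIVITY_SCALES = ("raw", "log", "binary")


@dataclass(frozen=True)
class DatasetMetadata:
    """Per-dataset annotations.

    Parameters
    ----------
    name
        Short dataset identifier.
    substrate_library
        Whether the screened chemical library is made of non-natural
        ("industrial") substrates or natural metabolites ("physiological").
    activity_threshold
        Value above which a pair counts as active when binarizing.
    activity_scale
        Scale of the stored activity values: "raw", "log" or "binary".
    """

    name: str
    substrate_library: str = "industrial"
    activity_threshold: float = 0.0
    activity_scale: str = "raw"

    def __post_init__(self) -> None:
        if self.substrate_library not in SUBSTRATE_LIBRARIES:
            raise ValidationError(
                f"substrate_library must be one of {SUBSTRATE_LIBRARIES}, "
                f"got {self.substrate_library!r}"
            )
        if self.activity_scale not in ACTIVITY_SCALES:
            raise ValidationError(
                f"activity_scale must be one of {ACTIVITY_SCALES}, "
                f"got {self.activity_scale!r}"
            )
        if not math.isfinite(self.activity_threshold):
            raise ValidationError("activity_threshold must be finite")


def _validate_sequence(enzyme_id: str, sequence: str) -> None:
    if not sequence:
        raise ValidationError(f"enzyme {enzyme_id!r} has an empty sequence")
    bad = set(sequence) - VALID_RESIDUES
    if bad:
        raise ValidationError(
            f"enzyme {enzyme_id!r} contains invalid residues {sorted(bad)}"
        )


@dataclass
class ActivityDataset:
    """An enzyme family, a chemical library and their activity matrix.

    ``activity`` is a float array of shape (n_enzymes, n_chemicals); missing
    cells are NaN. Row order follows ``enzyme_ids``, column order
    ``chemical_ids``.
    """

    enzyme_ids: tuple[str, ...]
    sequences: tuple[str, ...]
    chemical_ids: tuple[str, ...]
    smiles: tuple[Optional[str], ...]
    activity: np.ndarray
    metadata: DatasetMetadata = field(
        default_factory=lambda: DatasetMetadata(name="unnamed")
    )

    def __post_init__(self) -> None:
        self.enzyme_ids = tuple(self.enzyme_ids)
        self.sequences = tuple(self.sequences)
        self.chemical_ids = tuple(self.chemical_ids)
        self.smiles = tuple(self.smiles)
        self.activity = np.asarray(self.activity, dtype=float)
        if len(self.enzyme_ids) != len(self.sequences):
            raise ValidationError("one sequence per enzyme id required")
        if len(self.chemical_ids) != len(self.smiles):
            raise ValidationError("one smiles entry per chemical id required")
        if self.activity.shape != (len(self.enzyme_ids), len(self.chemical_ids)):
            raise ValidationError(
                f"activity shape {self.activity.shape} does not match "
                f"{len(self.enzyme_ids)} enzymes x {len(self.chemical_ids)} chemicals"
            )
        if len(set(self.enzyme_ids)) != len(self.enzyme_ids):
            raise ValidationError("duplicate enzyme ids")
        if len(set(self.chemical_ids)) != len(self.chemical_ids):
            raise ValidationError("duplicate chemical ids")
        for eid, seq in zip(self.enzyme_ids, self.sequences):
            _validate_sequence(eid, seq)

    # -- convenience -------------------------------------------------------

    @property
    def n_enzymes(self) -> int:
        return len(self.enzyme_ids)

    @property
    def n_chemicals(self) -> int:
        return len(self.chemical_ids)

    @property
    def is_binary(self) -> bool:
        return self.metadata.activity_scale == "binary"

    def activity_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.activity, index=list(self.enzyme_ids), columns=list(self.chemical_ids)
        )

    def with_activity(
        self, activity: np.ndarray, metadata: DatasetMetadata
    ) -> "ActivityDataset":
        """Return a copy with a new matrix and metadata (ids shared)."""
        return ActivityDataset(
            enzyme_ids=self.enzyme_ids,
            sequences=self.sequences,
            chemical_ids=self.chemical_ids,
            smiles=self.smiles,
            activity=np.asarray(activity, dtype=float),
            metadata=metadata,
        )

    def subset(
        self,
        enzyme_indices: Sequence[int] | None = None,
        chemical_indices: Sequence[int] | None = None,
    ) -> "ActivityDataset":
        """Row/column subset preserving order of the given indices."""
        ei = list(range(self.n_enzymes)) if enzyme_indices is None else list(enzyme_indices)
        ci = list(range(self.n_chemicals)) if chemical_indices is None else list(chemical_indices)
        return ActivityDataset(
            enzyme_ids=tuple(self.enzyme_ids[i] for i in ei),
            sequences=tuple(self.sequences[i] for i in ei),
            chemical_ids=tuple(self.chemical_ids[j] for j in ci),
            smiles=tuple(self.smiles[j] for j in ci),
            activity=self.activity[np.ix_(ei, ci)],
            metadata=self.metadata,
        )


# -- transforms ------------------------------------------------------------


def binarize_activity(
    dataset: ActivityDataset, threshold: float | None = None
) -> ActivityDataset:
    """Threshold the activity matrix into active (1) / inactive (0).

    A non-missing cell becomes 1 when its value is strictly greater than
    ``threshold`` (default: the metadata threshold). Missing cells stay
    missing. On an already-binary dataset this is a no-op with a warning.
    """
    if dataset.is_binary:
        warnings.warn("dataset already binary; binarize_activity is a no-op")
        return dataset.with_activity(dataset.activity.copy(), dataset.metadata)
    if threshold is None:
        threshold = dataset.metadata.activity_threshold
    if not math.isfinite(threshold):
        raise DomainError("binarization threshold must be finite")
    values = dataset.activity
    out = np.where(np.isnan(values), np.nan, (values > threshold).astype(float))
    meta = replace(dataset.metadata, activity_scale="binary")
    return dataset.with_activity(out, meta)


def log_transform_activity(
    dataset: ActivityDataset, pseudocount: float = 1.0
) -> ActivityDataset:
    """Map each non-missing value v to log10(v + pseudocount)."""
    values = dataset.activity
    if np.nanmin(values) < 0:
        raise DomainError("log transform requires non-negative activities")
    out = np.where(np.isnan(values), np.nan, np.log10(values + pseudocount))
    meta = replace(dataset.metadata, activity_scale="log")
    return dataset.with_activity(out, meta)


# -- persistence -----------------------------------------------------------

_FILES = ("enzymes.fasta", "chemicals.csv", "activity.csv", "metadata.yaml")


def save_dataset(dataset: ActivityDataset, directory: str | Path) -> Path:
    """Write the dataset directory (four files); returns the directory path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    records = [
        SeqRecord(Seq(seq), id=eid, description="")
        for eid, seq in zip(dataset.enzyme_ids, dataset.sequences)
    ]
    SeqIO.write(records, directory / "enzymes.fasta", "fasta")

    pd.DataFrame(
        {
            "chemical_id": list(dataset.chemical_ids),
            "smiles": ["" if s is None else s for s in dataset.smiles],
        }
    ).to_csv(directory / "chemicals.csv", index=False)

    dataset.activity_frame().to_csv(
        directory / "activity.csv", na_rep="NA", index_label="enzyme_id"
    )

    meta = dataset.metadata
    with open(directory / "metadata.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "name": meta.name,
                "substrate_library": meta.substrate_library,
                "activity_threshold": float(meta.activity_threshold),
                "activity_scale": meta.activity_scale,
            },
            fh,
            sort_keys=False,
        )
    return directory


def load_dataset(directory: str | Path) -> ActivityDataset:
    """Read a dataset directory written by :func:`save_dataset`.

    The activity matrix is re-aligned to the id orders of enzymes.fasta and
    chemicals.csv; an id present in one file but not the other raises
    :class:`ConsistencyError`.
    """
    directory = Path(directory)
    for fname in _FILES:
        if not (directory / fname).exists():
            raise DatasetLoadError(f"missing dataset file: {directory / fname}")

    records = list(SeqIO.parse(directory / "enzymes.fasta", "fasta"))
    enzyme_ids = [r.id for r in records]
    sequences = [str(r.seq) for r in records]

    chem = pd.read_csv(
        directory / "chemicals.csv", dtype=str, keep_default_na=False, na_values=[]
    )
    if list(chem.columns[:2]) != ["chemical_id", "smiles"]:
        raise DatasetLoadError("chemicals.csv must have header chemical_id,smiles")
    chemical_ids = chem["chemical_id"].tolist()
    smiles = [s if s else None for s in chem["smiles"].tolist()]

    act = pd.read_csv(
        directory / "activity.csv",
        index_col=0,
        keep_default_na=False,
        na_values=["", "NA"],
    )
    if set(act.columns) != set(chemical_ids):
        raise ConsistencyError(
            "activity.csv column ids do not match chemicals.csv chemical_ids"
        )
    if set(act.index.astype(str)) != set(enzyme_ids):
        raise ConsistencyError(
            "activity.csv row ids do not match enzymes.fasta ids"
        )
    act = act.loc[enzyme_ids, chemical_ids]

    with open(directory / "metadata.yaml", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    metadata = DatasetMetadata(
        name=str(raw.get("name", directory.name)),
        substrate_library=str(raw.get("substrate_library", "industrial")),
        activity_threshold=float(raw.get("activity_threshold", 0.0)),
        activity_scale=str(raw.get("activity_scale", "raw")),
    )

    return ActivityDataset(
        enzyme_ids=tuple(enzyme_ids),
        sequences=tuple(sequences),
        chemical_ids=tuple(chemical_ids),
        smiles=tuple(smiles),
        activity=act.to_numpy(dtype=float),
        metadata=metadata,
    )
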