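"""Numeric descriptors for enzymes and chemicals, plus the two
information-destroying randomization strategies used for ablation.

Sequence descriptors are composition-based: amino-acid composition (AAC, 20
dims), grouped amino-acid composition over five physicochemical classes
(GAAC, 5 dims) and grouped dipeptide composition (GDPC, 25 dims); their
concatenation is the 50-dimensional ``composition50`` descriptor. Chemical
descriptors are 2048-bit Morgan fingerprints or a fixed panel of 2-D
physicochemical properties. External descriptors (e.g. precomputed language
-model embeddings) enter through a CSV file or an in-memory table and are
aligned to the dataset's object order.

The two randomizations are the ablation levers:

* ``shuffle_sequences`` permutes the residues within each sequence --
  destroying order information while preserving per-sequence composition;
* ``permute_table`` reassigns whole descriptor rows to object ids by one
  random bijection -- descriptors then still identify objects seen in
  training but carry no transferable information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .dataset_io import AA_ALPHABET
from .dataset_statistics import _FP_GEN, _mol_from_smiles
from .exceptions import DomainError, LookupError_, ValidationError

#: iFeature-style five-class physicochemical grouping of amino acids.
AA_GROUPS: dict[str, str] = {
    "aliphatic": "GAVLMI",
    "aromatic": "FYW",
    "positive": "KRH",
    "negative": "DE",
    "uncharged": "STCPNQ",
}
GROUP_NAMES = tuple(AA_GROUPS)
_AA_TO_GROUP = {aa: g for g, members in AA_GROUPS.items() for aa in members}

#: 2-D physicochemical property panel for chemicals, in column order.
PHYSCHEM_PROPERTIES = (
    "mol_weight",
    "logp",
    "h_bond_donors",
    "h_bond_acceptors",
    "tpsa",
    "ring_count",
    "rotatable_bonds",
    "heavy_atom_count",
)


@dataclass
class DescriptorTable:
    """Object-id -> fixed-length numeric vector mapping.

    ``provenance`` records whether the table is the regular computed one or
    the product of a randomization strategy (with its seed).
    """

    object_ids: tuple[str, ...]
    vectors: np.ndarray
    descriptor_name: str
    provenance: str = "regular"  # regular | shuffled | permuted
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.object_ids = tuple(self.object_ids)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.object_ids):
            raise ValidationError("one vector per object id required")
        if self.provenance not in ("regular", "shuffled", "permuted"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        if self.provenance in ("shuffled", "permuted") and self.seed is None:
            raise ValidationError("randomized tables must record their seed")
        self._index = {oid: i for i, oid in enumerate(self.object_ids)}

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def vector(self, object_id: str) -> np.ndarray:
        try:
            return self.vectors[self._index[object_id]]
        except KeyError:
            raise LookupError_(f"unknown object id {object_id!r}") from None

    def rows(self, object_ids: Sequence[str]) -> np.ndarray:
        try:
            idx = [self._index[o] for o in object_ids]
        except KeyError as exc:
            raise LookupError_(f"unknown object id {exc.args[0]!r}") from None
        return self.vectors[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.vectors, index=list(self.object_ids))


@dataclass
class DescriptorSpec:
    """Which descriptor to build and with what parameters.

    kinds: aac | gaac | gdpc | composition50 | chem_fingerprint |
    chem_physchem | external. Kind ``external`` needs either a ``path``
    (CSV: first column object_id, remaining columns numeric) or an in-memory
    ``table`` (DataFrame indexed by object_id) parameter.
    """

    kind: str
    parameters: dict = field(default_factory=dict)

    _KINDS = (
        "aac",
        "gaac",
        "gdpc",
        "composition50",
        "chem_fingerprint",
        "chem_physchem",
        "external",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValidationError(f"unknown descriptor kind {self.kind!r}")
        if self.kind == "external" and not (
            "path" in self.parameters or "table" in self.parameters
        ):
            raise ValidationError("external descriptor needs a 'path' or 'table'")


# -- sequence composition descriptors --------------------------------------


def _clean(sequence: str) -> str:
    """Drop ambiguous X residues; error if nothing informative remains."""
    kept = sequence.replace("X", "")
    if not kept:
        raise DomainError("sequence contains no unambiguous residues")
    return kept


def aac_descriptor(sequence: str) -> np.ndarray:
    """Amino-acid composition: 20 fractions in alphabetical residue order."""
    if not sequence:
        raise DomainError("empty sequence")
    seq = _clean(sequence)
    counts = np.array([seq.count(aa) for aa in AA_ALPHABET], dtype=float)
    return counts / len(seq)


def gaac_descriptor(sequence: str) -> np.ndarray:
    """Grouped amino-acid composition over the five physicochemical groups."""
    if not sequence:
        raise DomainError("empty sequence")
    seq = _clean(sequence)
    counts = np.zeros(5)
    for aa in seq:
        counts[GROUP_NAMES.index(_AA_TO_GROUP[aa])] += 1
    return counts / len(seq)


def gdpc_descriptor(sequence: str) -> np.ndarray:
    """Grouped dipeptide composition: 25 ordered group-pair frequencies.

    Adjacent dipeptides containing an X residue are dropped before
    normalization.
    """
    if len(sequence) < 2:
        raise DomainError("gdpc needs a sequence of length >= 2")
    pairs = [
        (sequence[i], sequence[i + 1])
        for i in range(len(sequence) - 1)
        if "X" not in sequence[i : i + 2]
    ]
    if not pairs:
        raise DomainError("no unambiguous dipeptides in sequence")
    counts = np.zeros((5, 5))
    for a, b in pairs:
        counts[GROUP_NAMES.index(_AA_TO_GROUP[a]), GROUP_NAMES.index(_AA_TO_GROUP[b])] += 1
    return (counts / len(pairs)).ravel()


def composition50_descriptor(sequence: str) -> np.ndarray:
    """AAC ++ GAAC ++ GDPC, the 50-dimensional composition descriptor."""
    return np.concatenate(
        [aac_descriptor(sequence), gaac_descriptor(sequence), gdpc_descriptor(sequence)]
    )


_SEQ_BUILDERS = {
    "aac": aac_descriptor,
    "gaac": gaac_descriptor,
    "gdpc": gdpc_descriptor,
    "composition50": composition50_descriptor,
}


def _load_external(object_ids: Sequence[str], spec: DescriptorSpec) -> np.ndarray:
    if "table" in spec.parameters:
        frame = spec.parameters["table"]
        if not isinstance(frame, pd.DataFrame):
            raise ValidationError("external 'table' must be a DataFrame")
    else:
        frame = pd.read_csv(Path(spec.parameters["path"]), index_col=0)
    frame.index = frame.index.astype(str)
    missing = [o for o in object_ids if o not in frame.index]
    if missing:
        raise LookupError_(f"external descriptor file missing ids {missing[:5]}")
    return frame.loc[list(object_ids)].to_numpy(dtype=float)


def build_sequence_table(
    object_ids: Sequence[str], sequences: Sequence[str], spec: DescriptorSpec
) -> DescriptorTable:
    """Build the enzyme descriptor table in dataset order."""
    if spec.kind in _SEQ_BUILDERS:
        builder = _SEQ_BUILDERS[spec.kind]
        vectors = np.stack([builder(s) for s in sequences])
    elif spec.kind == "external":
        vectors = _load_external(object_ids, spec)
    else:
        raise ValidationError(f"{spec.kind!r} is not a sequence descriptor")
    return DescriptorTable(tuple(object_ids), vectors, descriptor_name=spec.kind)


# -- chemical descriptors ---------------------------------------------------


def _physchem_vector(mol) -> np.ndarray:
    return np.array(
        [
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            Lipinski.NumHDonors(mol),
            Lipinski.NumHAcceptors(mol),
            rdMolDescriptors.CalcTPSA(mol),
            rdMolDescriptors.CalcNumRings(mol),
            Lipinski.NumRotatableBonds(mol),
            mol.GetNumHeavyAtoms(),
        ],
        dtype=float,
    )


def build_chemical_table(
    object_ids: Sequence[str], smiles_list: Sequence[Optional[str]], spec: DescriptorSpec
) -> DescriptorTable:
    """Build the chemical descriptor table in dataset order.

    ``chem_fingerprint`` yields 2048-bit chirality-aware Morgan fingerprints
    as 0/1 vectors; ``chem_physchem`` the fixed 2-D property panel
    (:data:`PHYSCHEM_PROPERTIES`); ``external`` loads vectors from file or
    DataFrame.
    """
    if spec.kind == "external":
        vectors = _load_external(object_ids, spec)
    elif spec.kind in ("chem_fingerprint", "chem_physchem"):
        mols = [
            _mol_from_smiles(s, cid) if s is not None else None
            for cid, s in zip(object_ids, smiles_list)
        ]
        for cid, mol in zip(object_ids, mols):
            if mol is None:
                raise DomainError(f"chemical {cid!r} has no SMILES")
        if spec.kind == "chem_fingerprint":
            vectors = np.stack(
                [np.array(_FP_GEN.GetFingerprint(m), dtype=float) for m in mols]
            )
        else:
            vectors = np.stack([_physchem_vector(m) for m in mols])
    else:
        raise ValidationError(f"{spec.kind!r} is not a chemical descriptor")
    return DescriptorTable(tuple(object_ids), vectors, descriptor_name=spec.kind)


# -- randomization strategies ----------------------------------------------


def shuffle_sequences(sequences: Sequence[str], seed: int) -> list[str]:
    """Independently permute the residues of each sequence (shuffle strategy).

    Deterministic given the seed; length and residue multiset are preserved
    per sequence, so composition descriptors (AAC, GAAC) are unchanged while
    order-dependent information is destroyed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for seq in sequences:
        chars = np.array(list(seq))
        out.append("".join(chars[rng.permutation(len(chars))]))
    return out


def permute_table(table: DescriptorTable, seed: int) -> DescriptorTable:
    """Reassign descriptor rows to object ids by one random bijection.

    The multiset of vectors is preserved; the object <-> descriptor
    correspondence is destroyed (permutation strategy).
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(table.object_ids))
    return DescriptorTable(
        object_ids=table.object_ids,
        vectors=table.vectors[perm],
        descriptor_name=table.descriptor_name,
        provenance="permuted",
        seed=int(seed),
    )


def concat_pair_features(
    enzyme_table: DescriptorTable,
    chemical_table: DescriptorTable,
    pairs: Sequence[tuple[str, str]],
) -> np.ndarray:
    """Per-pair feature rows: enzyme vector ++ chemical vector.

    Column order is the enzyme block then the chemical block. An empty pair
    list yields a well-formed 0-row matrix.
    """
    d = enzyme_table.dimension + chemical_table.dimension
    if not pairs:
        return np.empty((0, d))
    e_ids, c_ids = zip(*pairs)
    return np.hstack([enzyme_table.rows(e_ids), chemical_table.rows(c_ids)])
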