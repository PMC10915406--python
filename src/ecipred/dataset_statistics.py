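"""Dataset-characterization indicators.

Seven indicators summarize an activity dataset: the numbers of enzymes and
chemicals (after any scenario filtering), the activity ratio, two
activity-order concordance indices (AOIE over the enzyme axis, AOIC over the
chemical axis), and the mean top-5 pairwise similarity of enzymes
(Smith-Waterman) and chemicals (Morgan/Tanimoto).

AOIE measures how consistently individual chemicals rank the enzymes the way
the whole library ranks them: 0.5 for i.i.d. random activities, 1 when every
chemical induces the global enzyme order (a family with no chemical
specificity). AOIC is the same quantity with the two axes exchanged. Both
are pairwise-concordance fractions -- equivalently (Kendall tau + 1)/2
without tie correction -- with tied pairs contributing 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit import DataStructs

from .dataset_io import ActivityDataset, binarize_activity
from .exceptions import DomainError, UndefinedStatisticError

SCENARIOS = ("LOOT", "LPOT", "LCOT")


# -- activity-based indicators --------------------------------------------


def activity_ratio(activity_matrix: np.ndarray, binary: bool | None = None) -> float:
    """Fraction of active pairs (binary data) or mean activity (continuous).

    Missing (NaN) cells are excluded. ``binary=None`` auto-detects a 0/1
    matrix.
    """
    m = np.asarray(activity_matrix, dtype=float)
    vals = m[~np.isnan(m)]
    if vals.size == 0:
        raise UndefinedStatisticError("all activity cells are missing")
    if binary is None:
        binary = bool(np.isin(vals, (0.0, 1.0)).all())
    if binary:
        return float(np.mean(vals == 1.0))
    return float(np.mean(vals))


def _column_concordance(col: np.ndarray, global_scores: np.ndarray) -> float:
    """Mean pairwise concordance of one column's order with the global order.

    Pairs with a tie on either side count 0.5; pairs with a missing cell are
    excluded. A column with fewer than two non-missing cells (hence no
    rankable pair) contributes the neutral value 0.5.
    """
    ok = ~np.isnan(col)
    idx = np.flatnonzero(ok)
    if idx.size < 2:
        return 0.5
    v = col[idx]
    g = global_scores[idx]
    dv = np.sign(v[:, None] - v[None, :])
    dg = np.sign(g[:, None] - g[None, :])
    iu = np.triu_indices(idx.size, k=1)
    prod = dv[iu] * dg[iu]
    # concordant -> 1, discordant -> 0, tie on either side -> 0.5
    return float(np.mean(np.where(prod > 0, 1.0, np.where(prod < 0, 0.0, 0.5))))


def aoie(activity_matrix: np.ndarray) -> float:
    """Activity Order Index at the Enzyme axis.

    For each chemical, the ordering of enzymes by that chemical's column is
    compared against the global enzyme ordering by row sums over non-missing
    cells of the *other* chemicals; the pairwise-concordance fractions are
    averaged over chemicals. Excluding the scored column from the global
    ranking keeps the index unbiased at 0.5 for i.i.d. random data (a column
    is trivially concordant with its own contribution to the row sum) while
    leaving fully order-consistent data at 1.
    """
    m = np.asarray(activity_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 1:
        raise UndefinedStatisticError("aoie requires a 2-D matrix with >=1 column")
    if m.shape[0] < 2:
        raise UndefinedStatisticError("aoie requires at least two enzymes")
    totals = np.nansum(m, axis=1)
    scores = []
    for j in range(m.shape[1]):
        col = m[:, j]
        global_scores = totals - np.where(np.isnan(col), 0.0, col)
        scores.append(_column_concordance(col, global_scores))
    return float(np.mean(scores))


def aoic(activity_matrix: np.ndarray) -> float:
    """Activity Order Index at the Chemical axis (AOIE of the transpose)."""
    m = np.asarray(activity_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 1:
        raise UndefinedStatisticError("aoic requires a 2-D matrix with >=1 row")
    if m.shape[1] < 2:
        raise UndefinedStatisticError("aoic requires at least two chemicals")
    return aoie(m.T)


# -- similarity indicators --------------------------------------------------


def _make_aligner(gap_open: float, gap_extend: float, matrix_name: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # first gap residue costs gap_open, each further residue gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_alignment_similarity(
    seq_a: str,
    seq_b: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    matrix_name: str = "BLOSUM62",
) -> float:
    """Normalized Smith-Waterman similarity of two protein sequences.

    Returns SW(a, b) / sqrt(SW(a, a) * SW(b, b)) under BLOSUM62 with affine
    gaps (a gap of length k costs open + (k-1) * extend). Symmetric, 1.0 for
    identical sequences.
    """
    if not seq_a or not seq_b:
        raise DomainError("sequences must be non-empty")
    aligner = _make_aligner(gap_open, gap_extend, matrix_name)
    ab = aligner.score(seq_a, seq_b)
    aa = aligner.score(seq_a, seq_a)
    bb = aligner.score(seq_b, seq_b)
    return float(ab / math.sqrt(aa * bb))


def protein_similarity_matrix(
    sequences: Sequence[str], **kwargs
) -> np.ndarray:
    """Square symmetric matrix of normalized Smith-Waterman similarities."""
    n = len(sequences)
    aligner = _make_aligner(
        kwargs.get("gap_open", 11.0),
        kwargs.get("gap_extend", 1.0),
        kwargs.get("matrix_name", "BLOSUM62"),
    )
    self_scores = np.array([aligner.score(s, s) for s in sequences])
    sim = np.ones((n, n))
    for i, j in combinations(range(n), 2):
        s = aligner.score(sequences[i], sequences[j])
        sim[i, j] = sim[j, i] = s / math.sqrt(self_scores[i] * self_scores[j])
    return sim


_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(
    radius=2, fpSize=2048, includeChirality=True
)


def _mol_from_smiles(smiles: str, chem_id: Optional[str] = None):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        label = chem_id if chem_id is not None else smiles
        raise DomainError(f"unparseable SMILES for chemical {label!r}")
    return mol


def morgan_tanimoto_similarity(smiles_a: str, smiles_b: str) -> float:
    """Tanimoto similarity of chirality-aware 2048-bit Morgan fingerprints.

    Radius 2 (ECFP4-like); 1.0 for identical molecules.
    """
    fa = _FP_GEN.GetFingerprint(_mol_from_smiles(smiles_a))
    fb = _FP_GEN.GetFingerprint(_mol_from_smiles(smiles_b))
    return float(DataStructs.TanimotoSimilarity(fa, fb))


def chemical_similarity_matrix(
    smiles_list: Sequence[str], ids: Sequence[str] | None = None
) -> np.ndarray:
    """Square symmetric Tanimoto similarity matrix over a SMILES list."""
    fps = []
    for k, s in enumerate(smiles_list):
        cid = ids[k] if ids is not None else None
        fps.append(_FP_GEN.GetFingerprint(_mol_from_smiles(s, cid)))
    n = len(fps)
    sim = np.ones((n, n))
    for i in range(n):
        if i + 1 < n:
            row = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :])
            sim[i, i + 1 :] = row
            sim[i + 1 :, i] = row
    return sim


def topk_mean_similarity(similarity_matrix: np.ndarray, k: int = 5) -> float:
    """Mean over objects of the mean of each object's k largest neighbours.

    The diagonal (self-similarity) is excluded; objects with fewer than k
    neighbours use all of them.
    """
    s = np.asarray(similarity_matrix, dtype=float)
    n = s.shape[0]
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise DomainError("similarity matrix must be square")
    if n < 2:
        raise UndefinedStatisticError("top-k similarity needs >=2 objects")
    per_object = []
    for i in range(n):
        neigh = np.delete(s[i], i)
        kk = min(k, neigh.size)
        top = np.sort(neigh)[-kk:]
        per_object.append(top.mean())
    return float(np.mean(per_object))


# -- the seven indicators ---------------------------------------------------


@dataclass(frozen=True)
class DatasetStatistics:
    """The seven indicators for one dataset under one evaluation scenario."""

    n_enzymes: int
    n_chemicals: int
    activity_ratio: float
    aoie: float
    aoic: float
    top5_protein_similarity: float
    top5_chemical_similarity: float

    def as_dict(self) -> dict:
        return {
            "n_enzymes": self.n_enzymes,
            "n_chemicals": self.n_chemicals,
            "activity_ratio": self.activity_ratio,
            "aoie": self.aoie,
            "aoic": self.aoic,
            "top5_protein_similarity": self.top5_protein_similarity,
            "top5_chemical_similarity": self.top5_chemical_similarity,
        }


def compute_statistics(
    dataset: ActivityDataset, scenario: str = "LOOT", k: int = 5
) -> DatasetStatistics:
    """Compute all seven indicators under a scenario's object filtering.

    LOOT uses the full dataset; LPOT drops chemicals (and LCOT enzymes) that
    fail the activity-count balance filter used before splitting. When a
    dataset carries no SMILES the chemical-similarity indicator is NaN.
    """
    from .evaluation import filter_for_scenario  # local import: no cycle at load

    if scenario not in SCENARIOS:
        raise DomainError(f"scenario must be one of {SCENARIOS}")
    binary = dataset if dataset.is_binary else binarize_activity(dataset)
    e_idx, c_idx = filter_for_scenario(binary.activity, scenario)
    sub = dataset.subset(e_idx, c_idx)

    ratio = activity_ratio(sub.activity, binary=sub.is_binary)
    prot_sim = protein_similarity_matrix(sub.sequences)
    if all(s is not None for s in sub.smiles) and sub.n_chemicals >= 2:
        chem_sim = chemical_similarity_matrix(sub.smiles, sub.chemical_ids)
        top5_chem = topk_mean_similarity(chem_sim, k=k)
    else:
        top5_chem = float("nan")
    return DatasetStatistics(
        n_enzymes=sub.n_enzymes,
        n_chemicals=sub.n_chemicals,
        activity_ratio=ratio,
        aoie=aoie(sub.activity),
        aoic=aoic(sub.activity),
        top5_protein_similarity=topk_mean_similarity(prot_sim, k=k),
        top5_chemical_similarity=top5_chem,
    )
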