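"""Sequence-based kinase scoring: position weight matrices and a BLOSUM62
k-nearest-neighbor classifier over 15-mer phosphosite windows."""

from __future__ import annotations

import json
import math
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import AA20, PAD, WINDOW_LENGTH, PhosphoSite

AA_INDEX = {aa: i for i, aa in enumerate(AA20)}

#: score assigned to log2(0) cells when no pseudocount is used
LOG_FLOOR = -10.0

DEFAULT_K_FRACTION = 0.075

_BLOSUM62 = None


def blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def load_matrix(path: str | Path):
    """Load an alternative substitution matrix in NCBI text format."""
    return substitution_matrices.read(str(path))


def uniform_background() -> dict[str, float]:
    return {aa: 1.0 / 20.0 for aa in AA20}


def pooled_background(peptides: Iterable[str]) -> dict[str, float]:
    """Amino-acid frequencies pooled over all non-padding residues.

    Residues outside the standard 20 letters are ignored.
    """
    counts = {aa: 0 for aa in AA20}
    total = 0
    for pep in peptides:
        for ch in pep:
            if ch in counts:
                counts[ch] += 1
                total += 1
    if total == 0:
        raise ValueError("no standard residues found; cannot pool background")
    return {aa: c / total for aa, c in counts.items()}


@dataclass
class PWMModel:
    """Per-kinase 20 x 15 log2-likelihood matrix.

    Rows follow :data:`~ksp.io_formats.AA20` order; columns are window
    positions -7..+7.
    """

    kinase_id: str
    matrix: np.ndarray
    background: dict[str, float]
    alpha: float
    n_sites: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (20, WINDOW_LENGTH):
            raise ValueError(
                f"matrix must be 20x{WINDOW_LENGTH}, got {self.matrix.shape}"
            )


def build_pwm(
    peptides: Sequence[str],
    kinase_id: str = "",
    background: Mapping[str, float] | None = None,
    alpha: float = 0.0,
) -> PWMModel:
    """Build a PWM from 15-mer peptides.

    Cell (k, j) is ``log2((count_kj + alpha) / ((N_j + 20*alpha) * b_k))``
    where ``N_j`` is the number of observed (non-padding, standard-letter)
    residues in column j, so each column's probability profile sums to 1.
    With ``alpha == 0``, unobserved cells are floored at ``LOG_FLOOR``.
    """
    if not peptides:
        raise ValueError("cannot build a PWM from an empty peptide list")
    if alpha < 0:
        raise ValueError("pseudocount alpha must be >= 0")
    for pep in peptides:
        if len(pep) != WINDOW_LENGTH:
            raise ValueError(f"peptide {pep!r} is not a {WINDOW_LENGTH}-mer")
    if background is None:
        bg = pooled_background(peptides)
    else:
        bg = dict(background)
        missing = [aa for aa in AA20 if aa not in bg]
        if missing:
            raise ValueError(f"background is missing residues {missing}")

    counts = np.zeros((20, WINDOW_LENGTH))
    for pep in peptides:
        for j, ch in enumerate(pep):
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx, j] += 1.0

    n_obs = counts.sum(axis=0)  # per-column observed residues
    denom = n_obs + 20.0 * alpha
    matrix = np.full((20, WINDOW_LENGTH), LOG_FLOOR)
    for i, aa in enumerate(AA20):
        b = bg[aa]
        if b <= 0:
            continue
        for j in range(WINDOW_LENGTH):
            numer = counts[i, j] + alpha
            if numer > 0 and denom[j] > 0:
                matrix[i, j] = math.log2(numer / (denom[j] * b))
    return PWMModel(
        kinase_id=kinase_id,
        matrix=matrix,
        background=bg,
        alpha=alpha,
        n_sites=len(peptides),
    )


def pwm_score(model: PWMModel, peptide: str) -> float:
    """Sum of matrix entries along the peptide; padding/unknowns add 0."""
    if len(peptide) != WINDOW_LENGTH:
        raise ValueError(f"peptide {peptide!r} is not a {WINDOW_LENGTH}-mer")
    total = 0.0
    for j, ch in enumerate(peptide):
        idx = AA_INDEX.get(ch)
        if idx is not None:
            total += model.matrix[idx, j]
    return total


def train_pwm_models(
    sites_by_kinase: Mapping[str, Sequence[PhosphoSite]],
    background: str | Mapping[str, float] = "pooled",
    alpha: float = 0.0,
) -> list[PWMModel]:
    """Build one PWM per kinase with a background shared across kinases.

    ``background`` is ``"pooled"`` (frequencies over all training peptides),
    ``"uniform"``, or an explicit mapping.
    """
    if isinstance(background, str):
        if background == "pooled":
            bg = pooled_background(
                s.peptide for sites in sites_by_kinase.values() for s in sites
            )
        elif background == "uniform":
            bg = uniform_background()
        else:
            raise ValueError(f"unknown background {background!r}")
    else:
        bg = dict(background)
    return [
        build_pwm([s.peptide for s in sites], kinase_id=k, background=bg, alpha=alpha)
        for k, sites in sorted(sites_by_kinase.items())
    ]


def blosum_similarity(s1: str, s2: str, matrix=None) -> int:
    """Positionwise substitution-matrix similarity of two 15-mers.

    Returns 0 whenever either peptide has fewer than 7 real residues on
    either side of the center (i.e. contains padding).
    """
    if len(s1) != WINDOW_LENGTH or len(s2) != WINDOW_LENGTH:
        raise ValueError("both peptides must be 15-mers")
    if PAD in s1 or PAD in s2:
        return 0
    m = matrix if matrix is not None else blosum62()
    total = 0
    alphabet = m.alphabet
    for a, b in zip(s1, s2):
        if a in alphabet and b in alphabet:
            total += int(m[a, b])
    return total


@dataclass
class TrainingCorpus:
    """Labeled 15-mer training set for nearest-neighbor queries.

    Peptides are deduplicated per kinase; one peptide may carry several
    kinase labels via separate entries.
    """

    entries: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        unique: list[tuple[str, str]] = []
        for pep, kin in self.entries:
            if (pep, kin) not in seen:
                seen.add((pep, kin))
                unique.append((pep, kin))
        self.entries = unique

    @classmethod
    def from_sites(
        cls, sites_by_kinase: Mapping[str, Sequence[PhosphoSite]]
    ) -> "TrainingCorpus":
        return cls(
            [
                (s.peptide, kin)
                for kin, sites in sorted(sites_by_kinase.items())
                for s in sites
            ]
        )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def kinases(self) -> set[str]:
        return {kin for _, kin in self.entries}


def knn_size(corpus_size: int, k_fraction: float) -> int:
    """Half-up rounding of ``k_fraction * corpus_size``, floored at 1."""
    if not 0 < k_fraction <= 1:
        raise ValueError("k_fraction must lie in (0, 1]")
    return max(1, math.floor(k_fraction * corpus_size + 0.5))


def cbs_score(
    corpus: TrainingCorpus,
    peptide: str,
    k_fraction: float = DEFAULT_K_FRACTION,
    matrix=None,
) -> dict[str, float]:
    """Fraction of the query's k nearest training peptides per kinase.

    Neighbors are the k corpus entries with the largest similarity to the
    query; ties at the cutoff break lexicographically by (peptide, kinase).
    Only kinases appearing in the neighborhood are present in the result.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    k = knn_size(len(corpus), k_fraction)
    if PAD in peptide:
        warnings.warn(
            "query peptide has fewer than 7 real flanking residues; all "
            "similarities are 0",
            stacklevel=2,
        )
    sims = [
        (blosum_similarity(peptide, pep, matrix=matrix), pep, kin)
        for pep, kin in corpus.entries
    ]
    sims.sort(key=lambda t: (-t[0], t[1], t[2]))
    scores: dict[str, float] = {}
    for _, _, kin in sims[:k]:
        scores[kin] = scores.get(kin, 0.0) + 1.0
    return {kin: c / k for kin, c in scores.items()}


def rank_kinases_sequence(
    models: Sequence[PWMModel],
    corpus: TrainingCorpus,
    peptide: str,
    top_k: int = 10,
    k_fraction: float = DEFAULT_K_FRACTION,
    matrix=None,
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Rank kinases for a query by PWM score and by CBS score.

    Returns (pwm_ranked, cbs_ranked), each sorted descending with
    lexicographic tie-break and truncated to ``top_k``.
    """
    if not models:
        raise ValueError("at least one PWM model is required")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    pwm_scores = {m.kinase_id: pwm_score(m, peptide) for m in models}
    cbs = cbs_score(corpus, peptide, k_fraction=k_fraction, matrix=matrix)
    cbs_scores = {kin: cbs.get(kin, 0.0) for kin in corpus.kinases}
    key = lambda kv: (-kv[1], kv[0])
    return (
        sorted(pwm_scores.items(), key=key)[:top_k],
        sorted(cbs_scores.items(), key=key)[:top_k],
    )


# -- persistence --------------------------------------------------------------

def save_pwm_models(models: Sequence[PWMModel], out_dir: str | Path) -> None:
    """Write each model as a TSV matrix plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    positions = [str(p) for p in range(-7, 8)]
    for m in models:
        base = out / m.kinase_id
        with open(f"{base}.pwm.tsv", "wt") as fh:
            fh.write("aa\t" + "\t".join(positions) + "\n")
            for i, aa in enumerate(AA20):
                row = "\t".join(repr(float(x)) for x in m.matrix[i])
                fh.write(f"{aa}\t{row}\n")
        with open(f"{base}.pwm.json", "wt") as fh:
            json.dump(
                {
                    "kinase_id": m.kinase_id,
                    "n_sites": m.n_sites,
                    "alpha": m.alpha,
                    "background": m.background,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def load_pwm_models(in_dir: str | Path) -> list[PWMModel]:
    models = []
    for meta_path in sorted(Path(in_dir).glob("*.pwm.json")):
        with open(meta_path) as fh:
            meta = json.load(fh)
        matrix = np.zeros((20, WINDOW_LENGTH))
        tsv = meta_path.with_name(meta_path.name.replace(".pwm.json", ".pwm.tsv"))
        with open(tsv) as fh:
            next(fh)
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                matrix[AA_INDEX[fields[0]]] = [float(x) for x in fields[1:]]
        models.append(
            PWMModel(
                kinase_id=meta["kinase_id"],
                matrix=matrix,
                background=meta["background"],
                alpha=meta["alpha"],
                n_sites=meta["n_sites"],
            )
        )
    if not models:
        raise ValueError(f"no PWM models found in {in_dir}")
    return models
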