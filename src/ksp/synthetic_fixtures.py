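"""Synthetic networks and peptide corpora with planted structure.

The generator plants (a) kinase-substrate links inside a heterogeneous
interaction network whose bystander proteins attach preferentially to
well-connected nodes, and (b) per-kinase sequence motifs: each kinase gets
a position frequency matrix drawn from a Dirichlet whose concentration on
a consensus residue is controlled by ``motif_sharpness``.  Everything is a
pure function of (spec, seed).
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from .io_formats import (
    AA20,
    CENTER_INDEX,
    WINDOW_LENGTH,
    KinaseSubstratePair,
    PPIEdge,
    PhosphoSite,
    write_kinase_substrate_table,
    write_ppi_table,
)

PHOSPHO_CENTERS = "STY"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    n_kinases: int = 30
    n_substrates: int = 300
    n_bystanders: int = 120
    sites_per_kinase: int = 18  # mean substrates per kinase (heavy-tailed)
    extra_site_rate: float = 1.0  # Poisson mean of extra sites per pair
    kinase_popularity: float = 1.4  # Zipf exponent of per-kinase substrate counts
    substrate_popularity: float = 0.3  # Zipf exponent of substrate choice
    ppi_attachment: float = 1.0  # preferential-attachment exponent
    ppi_edges_per_node: int = 1
    motif_sharpness: float = 25.0  # Dirichlet mass on the consensus residue
    motif_positions: int = 2  # max informative non-center positions per kinase
    motif_positions_min: int = 0  # min informative positions per kinase
    background: Mapping[str, float] | None = None  # None -> uniform
    n_negatives: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_kinases, self.n_substrates, self.sites_per_kinase) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_bystanders < 0 or self.n_negatives < 0:
            raise ValueError("counts must be >= 0")
        if self.motif_sharpness <= 0:
            raise ValueError("motif_sharpness must be > 0")
        if not 0 <= self.motif_positions <= WINDOW_LENGTH - 1:
            raise ValueError("motif_positions must lie in [0, 14]")
        if not 0 <= self.motif_positions_min <= self.motif_positions:
            raise ValueError("motif_positions_min must lie in [0, motif_positions]")
        if self.extra_site_rate < 0:
            raise ValueError("extra_site_rate must be >= 0")
        if self.background is not None:
            total = sum(self.background.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("background frequencies must sum to 1")

    def background_vector(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 1.0 / 20.0)
        return np.array([self.background.get(aa, 0.0) for aa in AA20])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class SyntheticDataset:
    spec: FixtureSpec
    pairs: list[KinaseSubstratePair]
    ppi: list[PPIEdge]
    truth: dict[tuple[str, int], str]  # (substrate, position) -> kinase
    positives_by_kinase: dict[str, list[PhosphoSite]] = field(default_factory=dict)
    negatives: list[PhosphoSite] = field(default_factory=list)


def _kinase_ids(spec: FixtureSpec) -> list[str]:
    return [f"K{i:03d}" for i in range(1, spec.n_kinases + 1)]


def _substrate_ids(spec: FixtureSpec) -> list[str]:
    return [f"P{i:04d}" for i in range(1, spec.n_substrates + 1)]


def _kinase_pfms(spec: FixtureSpec) -> dict[str, tuple[np.ndarray, str]]:
    """Per-kinase (20 x 15 PFM, center residue); independent of the other
    simulation streams so network and peptide draws stay consistent."""
    rng = np.random.default_rng([spec.seed, 101])
    bg = spec.background_vector()
    pfms: dict[str, tuple[np.ndarray, str]] = {}
    flank_positions = [j for j in range(WINDOW_LENGTH) if j != CENTER_INDEX]
    for kin in _kinase_ids(spec):
        # soft center preference: kinases overlap in S/T/Y usage, so the
        # center residue alone cannot identify the kinase
        center_probs = rng.dirichlet([3.0, 2.0, 1.0])
        pfm = np.tile(bg[:, None], (1, WINDOW_LENGTH))
        pfm[:, CENTER_INDEX] = 0.0
        for res, prob in zip(PHOSPHO_CENTERS, center_probs):
            pfm[AA20.index(res), CENTER_INDEX] = prob
        center = PHOSPHO_CENTERS[int(np.argmax(center_probs))]
        # informative-position count varies per kinase; with the default
        # lower bound of 0 some kinases are only recognizable through the
        # network, giving the two scorers complementary coverage
        n_pos = int(
            rng.integers(spec.motif_positions_min, spec.motif_positions + 1)
        )
        motif_at = rng.choice(len(flank_positions), size=n_pos, replace=False)
        for idx in motif_at:
            j = flank_positions[int(idx)]
            consensus = int(rng.integers(20))
            # large concentration on the consensus residue -> near-deterministic
            alpha = 20.0 * bg.copy()
            alpha[consensus] += spec.motif_sharpness
            pfm[:, j] = rng.dirichlet(alpha)
        pfms[kin] = (pfm, center)
    return pfms


def _sample_peptide(rng: np.random.Generator, pfm: np.ndarray) -> str:
    cols = [rng.choice(20, p=pfm[:, j] / pfm[:, j].sum()) for j in range(WINDOW_LENGTH)]
    return "".join(AA20[c] for c in cols)


def simulate_network(
    spec: FixtureSpec,
) -> tuple[list[KinaseSubstratePair], list[PPIEdge], dict[tuple[str, int], str]]:
    """Plant kinase-substrate links and wire bystanders preferentially.

    Returns (pairs, ppi edges, ground-truth kinase per (substrate, position)).
    Substrate popularity is heavy-tailed, so some substrates are shared by
    several kinases while most have few links.  Raises if the merged graph
    cannot be connected within 100 rewiring attempts.
    """
    rng = np.random.default_rng([spec.seed, 202])
    pfms = _kinase_pfms(spec)
    kinases = _kinase_ids(spec)
    substrates = _substrate_ids(spec)

    # Zipf-like substrate popularity drives shared substrates / hub nodes
    pop = 1.0 / np.arange(1, spec.n_substrates + 1) ** spec.substrate_popularity
    pop = pop / pop.sum()

    # heavy-tailed kinase sizes: a few "well-studied" kinases carry many
    # substrates, mirroring the skew of curated kinase-substrate data
    share = 1.0 / np.arange(1, spec.n_kinases + 1) ** spec.kinase_popularity
    share = share / share.sum()
    n_subs = np.maximum(
        2, np.round(share * spec.n_kinases * spec.sites_per_kinase).astype(int)
    )

    pairs: list[KinaseSubstratePair] = []
    truth: dict[tuple[str, int], str] = {}
    next_position: dict[str, int] = {s: 8 for s in substrates}
    for kin, size in zip(kinases, n_subs):
        pfm, _ = pfms[kin]
        chosen = rng.choice(
            spec.n_substrates,
            size=min(int(size), spec.n_substrates),
            replace=False,
            p=pop,
        )
        for s_idx in chosen:
            sub = substrates[int(s_idx)]
            n_sites = 1 + int(rng.poisson(spec.extra_site_rate))
            for _ in range(n_sites):
                pos = next_position[sub]
                next_position[sub] += WINDOW_LENGTH
                peptide = _sample_peptide(rng, pfm)
                site = PhosphoSite(
                    substrate_id=sub,
                    position=pos,
                    residue=peptide[CENTER_INDEX],
                    peptide=peptide,
                )
                pairs.append(KinaseSubstratePair(kinase_id=kin, site=site))
                truth[(sub, pos)] = kin

    g = nx.Graph()
    g.add_nodes_from(kinases)
    # substrates that received no site exist only if wired in by the PPI
    for p in pairs:
        g.add_edge(p.kinase_id, p.site.substrate_id)

    ppi: list[PPIEdge] = []

    def attach(node: str, m: int) -> None:
        existing = [x for x in g.nodes if x != node]
        deg = np.array([g.degree(x) + 1.0 for x in existing])
        w = deg ** spec.ppi_attachment
        w = w / w.sum()
        targets = rng.choice(len(existing), size=min(m, len(existing)),
                             replace=False, p=w)
        for t in targets:
            other = existing[int(t)]
            if not g.has_edge(node, other):
                g.add_edge(node, other)
                ppi.append(PPIEdge(node, other))

    for i in range(1, spec.n_bystanders + 1):
        node = f"B{i:04d}"
        g.add_node(node)
        attach(node, spec.ppi_edges_per_node)

    attempts = 0
    while not nx.is_connected(g):
        attempts += 1
        if attempts > 100:
            raise RuntimeError("could not connect the synthetic graph "
                               "within 100 rewiring attempts")
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        giant = comps[0]
        minor = comps[1]
        a = sorted(minor)[int(rng.integers(len(minor)))]
        giant_nodes = sorted(giant)
        deg = np.array([g.degree(x) + 1.0 for x in giant_nodes], dtype=float)
        b = giant_nodes[int(rng.choice(len(giant_nodes), p=deg / deg.sum()))]
        g.add_edge(a, b)
        ppi.append(PPIEdge(a, b))

    return pairs, ppi, truth


def simulate_peptides(
    spec: FixtureSpec,
) -> tuple[dict[str, list[PhosphoSite]], list[PhosphoSite]]:
    """Draw per-kinase positive peptides and background negative windows.

    Positives come from each kinase's planted PFM (on virtual substrate
    ids); negatives are background-composition windows with an S/T/Y
    center, attached to fresh non-phospho protein ids.
    """
    rng = np.random.default_rng([spec.seed, 303])
    pfms = _kinase_pfms(spec)
    bg = spec.background_vector()
    positives: dict[str, list[PhosphoSite]] = {}
    for kin in _kinase_ids(spec):
        pfm, _ = pfms[kin]
        sites = []
        for i in range(spec.sites_per_kinase):
            peptide = _sample_peptide(rng, pfm)
            sites.append(
                PhosphoSite(
                    substrate_id=f"X{kin}",
                    position=8 + i * WINDOW_LENGTH,
                    residue=peptide[CENTER_INDEX],
                    peptide=peptide,
                )
            )
        positives[kin] = sites
    negatives: list[PhosphoSite] = []
    for i in range(spec.n_negatives):
        cols = rng.choice(20, size=WINDOW_LENGTH, p=bg / bg.sum())
        peptide = list(AA20[c] for c in cols)
        center = PHOSPHO_CENTERS[int(rng.integers(len(PHOSPHO_CENTERS)))]
        peptide[CENTER_INDEX] = center
        negatives.append(
            PhosphoSite(
                substrate_id=f"N{i:04d}",
                position=8,
                residue=center,
                peptide="".join(peptide),
            )
        )
    return positives, negatives


def simulate_dataset(spec: FixtureSpec) -> SyntheticDataset:
    """Full dataset: planted network with motif-bearing peptides, plus
    held-out per-kinase positives and background negatives."""
    pairs, ppi, truth = simulate_network(spec)
    positives, negatives = simulate_peptides(spec)
    return SyntheticDataset(
        spec=spec,
        pairs=pairs,
        ppi=ppi,
        truth=truth,
        positives_by_kinase=positives,
        negatives=negatives,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Emit the dataset in the same TSV dialects the readers accept,
    with the ground truth serialized alongside."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_kinase_substrate_table(ds.pairs, out / "pairs.tsv", dialect="plain")
    write_ppi_table(ds.ppi, out / "ppi.tsv")
    with open(out / "truth.tsv", "wt") as fh:
        fh.write("substrate\tposition\tkinase\n")
        for (sub, pos), kin in sorted(ds.truth.items()):
            fh.write(f"{sub}\t{pos}\t{kin}\n")
    with open(out / "negatives.tsv", "wt") as fh:
        fh.write("substrate\tposition\tpeptide\n")
        for s in ds.negatives:
            fh.write(f"{s.substrate_id}\t{s.position}\t{s.peptide}\n")
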