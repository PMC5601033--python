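"""Synthetic peptidome generator.

Emits fully synthetic peak lists with known ground truth so the whole
annotation -> network -> screening pipeline can be exercised without
any external dataset.  The generator plants three kinds of peaks:

* standalone peptides — random compositions over the working alphabet;
* degradation chains — nested composition series (each member losing
  one residue), whose members share a latent intensity signal so that
  connected peaks correlate strongly, mimicking the bimodal
  edge-correlation structure of real degradation networks;
* decoys — masses rejection-sampled until they admit *no* decomposition
  at the working tolerance, guaranteeing the NONE category.

Intensities are log-normal around the latent signals: non-negative,
realistic dynamic range, and rank correlations directly controllable.
Defaults mirror a direct-infusion fermentation study: 45 samples
(15 groups x 3 replicates), compositions of length 1-7, and an ordinal
phenotype scored 5 (best) to 1 over five levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .alphabet import Alphabet, yeast_alphabet
from .composition import Composition, composition_mass
from .decompose import Decomposer
from .peaklist import PeakList, write_peaklist
from .screen import PhenotypeDesign

__all__ = [
    "SimulationConfig",
    "SimulatedPeptidome",
    "PhenotypeSimulation",
    "simulate_peptidome",
    "simulate_phenotype",
]

logger = logging.getLogger("pepnet")

_MAX_DECOY_ATTEMPTS = 100_000
_MAX_CHAIN_ATTEMPTS = 2_000


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic peptidome.

    edge_rho is the target Spearman correlation between members of the
    same degradation chain; it sits well above the usual evidence
    threshold (rho >= 0.8) so that sampling noise at n_samples does not
    push true chain edges below the filter.  background_rho is the
    target between unrelated peaks (0: independent profiles).
    """

    seed: int = 0
    alphabet: Alphabet = field(default_factory=yeast_alphabet)
    n_peptides: int = 40
    length_range: tuple[int, int] = (1, 7)
    n_chains: int = 4
    chain_length: int = 4  # nodes per planted chain
    n_decoys: int = 20
    n_samples: int = 45
    mass_noise_sd: float = 2e-5
    tolerance: float = 1e-4  # working annotation tolerance
    edge_rho: float = 0.9
    background_rho: float = 0.0
    # phenotype design: groups (strains) scored over ordinal levels
    n_groups: int = 15
    replicates: int = 3
    n_levels: int = 5
    effect_size: float = 1.5  # log-intensity shift per score SD
    spiked_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.mass_noise_sd < 0:
            raise ValueError("mass_noise_sd must be >= 0")
        for name in ("n_peptides", "n_chains", "chain_length", "n_decoys"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("length_range must satisfy 1 <= lo <= hi")
        if not (0 <= self.spiked_fraction <= 1):
            raise ValueError("spiked_fraction must lie in [0, 1]")
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups")
        if self.n_levels < 2 or self.n_levels > self.n_groups:
            raise ValueError("n_levels must lie in [2, n_groups]")


@dataclass
class SimulatedPeptidome:
    """A synthetic peak list with its ground truth."""

    peaks: PeakList
    truth: pd.DataFrame  # peak_id, kind, composition, chain
    planted_edges: list[tuple[str, str]]  # all within-chain dominance pairs
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "peaks": out_dir / "file1_peaks.txt",
            "truth": out_dir / "ground_truth.txt",
            "edges": out_dir / "planted_edges.txt",
        }
        write_peaklist(self.peaks, paths["peaks"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with paths["edges"].open("w") as fh:
            fh.write("source\ttarget\n")
            for u, v in self.planted_edges:
                fh.write(f"{u}\t{v}\n")
        return paths


@dataclass
class PhenotypeSimulation:
    """A spiked peak list plus its phenotype design and ground truth."""

    peaks: PeakList
    design: PhenotypeDesign
    truth: pd.DataFrame  # adds a 'spiked' column
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "peaks": out_dir / "file1_phenotype.txt",
            "design": out_dir / "design.txt",
            "truth": out_dir / "ground_truth_phenotype.txt",
        }
        write_peaklist(self.peaks, paths["peaks"])
        self.design.write(paths["design"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal Pearson correlation giving Spearman rho_s."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def _random_composition(
    rng: np.random.Generator, alphabet: Alphabet, length: int
) -> Composition:
    symbols = rng.choice(alphabet.symbols, size=length, replace=True)
    counts: dict[str, int] = {}
    for s in symbols:
        counts[s] = counts.get(s, 0) + 1
    return Composition(counts)


def _sample_chain(
    rng: np.random.Generator,
    alphabet: Alphabet,
    engine: Decomposer,
    config: SimulationConfig,
    taken: set[Composition],
) -> list[Composition]:
    """A nested composition series whose members are all uniquely
    decomposable at the working tolerance (so they survive as PDN nodes)."""
    lo_extra = 1  # last chain member keeps length >= 2 (free AAs get dropped)
    max_len = max(config.length_range[1], config.chain_length + lo_extra)
    for _ in range(_MAX_CHAIN_ATTEMPTS):
        start_len = int(rng.integers(config.chain_length + lo_extra, max_len + 1))
        chain = [_random_composition(rng, alphabet, start_len)]
        while len(chain) < config.chain_length:
            current = chain[-1]
            expanded = [s for s, c in current.items() for _ in range(c)]
            drop = rng.integers(0, len(expanded))
            counts = dict(current)
            sym = expanded[drop]
            counts[sym] -= 1
            chain.append(Composition(counts))
        if any(c in taken for c in chain):
            continue
        ok = True
        for comp in chain:
            mass = composition_mass(comp, alphabet)
            if len(engine.decompose(mass, config.tolerance)) != 1:
                ok = False  # ambiguous at tolerance; not a usable PDN node
                break
        if ok:
            return chain
    raise RuntimeError(
        "could not sample an unambiguous degradation chain; "
        "reduce tolerance or chain length"
    )


def _latent_intensities(
    rng: np.random.Generator,
    latent: np.ndarray,
    loading: float,
    base_log: float,
    scale: float = 1.0,
) -> np.ndarray:
    noise = rng.standard_normal(latent.size)
    x = loading * latent + np.sqrt(max(0.0, 1.0 - loading**2)) * noise
    return np.exp(base_log + scale * x)


def simulate_peptidome(config: SimulationConfig) -> SimulatedPeptidome:
    """Generate the synthetic peak list (deterministic given the seed)."""
    rng = np.random.default_rng(config.seed)
    alphabet = config.alphabet
    engine = Decomposer(alphabet)

    taken: set[Composition] = set()
    records: list[dict] = []  # kind, composition | None, chain id

    # --- degradation chains ---------------------------------------------
    chains: list[list[Composition]] = []
    for ci in range(config.n_chains):
        chain = _sample_chain(rng, alphabet, engine, config, taken)
        taken.update(chain)
        chains.append(chain)
        for comp in chain:
            records.append({"kind": "chain", "composition": comp, "chain": ci})

    # --- standalone peptides --------------------------------------------
    lo, hi = config.length_range
    n_added = 0
    guard = 0
    while n_added < config.n_peptides:
        guard += 1
        if guard > 100 * max(config.n_peptides, 1):
            raise RuntimeError("could not sample enough distinct compositions")
        comp = _random_composition(rng, alphabet, int(rng.integers(lo, hi + 1)))
        if comp in taken:
            continue
        taken.add(comp)
        records.append({"kind": "peptide", "composition": comp, "chain": None})
        n_added += 1

    # --- decoys ----------------------------------------------------------
    mass_lo, mass_hi = 150.0, 900.0
    for _ in range(config.n_decoys):
        for attempt in range(_MAX_DECOY_ATTEMPTS):
            m = float(rng.uniform(mass_lo, mass_hi))
            if not engine.decompose(m, config.tolerance):
                records.append({"kind": "decoy", "composition": None, "chain": None, "mass": m})
                break
        else:
            raise RuntimeError(
                "decoy rejection sampling exhausted; the tolerance window "
                "leaves no undecomposable mass gaps — use a smaller tolerance"
            )

    # --- masses -----------------------------------------------------------
    masses = []
    for r in records:
        if r["composition"] is None:
            masses.append(r["mass"])
        else:
            m = composition_mass(r["composition"], alphabet)
            if config.mass_noise_sd > 0:
                m += rng.normal(0.0, config.mass_noise_sd)
            masses.append(m)

    # --- intensities ------------------------------------------------------
    n = len(records)
    loading_edge = float(np.sqrt(_spearman_to_pearson(config.edge_rho)))
    loading_bg = float(
        np.sqrt(max(0.0, _spearman_to_pearson(config.background_rho)))
    )
    latents = {ci: rng.standard_normal(config.n_samples) for ci in range(config.n_chains)}
    bg_latent = rng.standard_normal(config.n_samples)
    intensities = np.zeros((n, config.n_samples))
    for i, r in enumerate(records):
        base_log = float(rng.uniform(np.log(1e4), np.log(1e7)))
        if r["kind"] == "chain":
            latent = latents[r["chain"]]
            loading = loading_edge
        else:
            latent = bg_latent
            loading = loading_bg
        intensities[i] = _latent_intensities(rng, latent, loading, base_log)

    # --- assemble ---------------------------------------------------------
    order = np.argsort(masses, kind="stable")
    ids = [f"P{k + 1:04d}" for k in range(n)]
    sample_names = [f"S{j + 1:02d}" for j in range(config.n_samples)]
    frame = pd.DataFrame(intensities[order], columns=sample_names)
    peaks = PeakList(ids, np.asarray(masses)[order], frame, "neutral")

    truth_rows = []
    id_of_comp: dict[Composition, str] = {}
    for rank, idx in enumerate(order):
        r = records[idx]
        comp = r["composition"]
        pid = ids[rank]
        if comp is not None:
            id_of_comp[comp] = pid
        truth_rows.append(
            {
                "peak_id": pid,
                "kind": r["kind"],
                "composition": "" if comp is None else comp.to_string(alphabet),
                "chain": "" if r["chain"] is None else str(r["chain"]),
            }
        )
    truth = pd.DataFrame(truth_rows)

    # planted edges: every within-chain dominance pair (the PDN connects
    # all nested pairs, not just consecutive losses)
    planted_edges = []
    for chain in chains:
        for i in range(len(chain)):
            for j in range(i + 1, len(chain)):
                planted_edges.append((id_of_comp[chain[i]], id_of_comp[chain[j]]))

    logger.info(
        "simulated %d peaks (%d chain members, %d peptides, %d decoys), "
        "%d planted edges",
        n,
        sum(len(c) for c in chains),
        config.n_peptides,
        config.n_decoys,
        len(planted_edges),
    )
    return SimulatedPeptidome(peaks, truth, planted_edges, config)


def simulate_phenotype(
    config: SimulationConfig,
    base: Optional[SimulatedPeptidome] = None,
) -> PhenotypeSimulation:
    """Spike phenotype trends into a synthetic peak list.

    Samples are organized as ``n_groups`` groups x ``replicates``
    replicates; groups are assigned ordinal scores cycling over
    ``n_levels`` levels (highest score first).  A ``spiked_fraction`` of
    the planted peptide features get a log-intensity shift proportional
    to the standardized group score (``effect_size`` per score SD), so
    their group means track the phenotype monotonically.
    """
    n_samples = config.n_groups * config.replicates
    if base is None:
        from dataclasses import replace

        base = simulate_peptidome(replace(config, n_samples=n_samples))
    if base.peaks.n_samples != n_samples:
        raise ValueError(
            f"base peak list has {base.peaks.n_samples} samples, but the "
            f"design needs n_groups * replicates = {n_samples}"
        )
    rng = np.random.default_rng(config.seed + 1)

    groups = [f"G{k + 1:02d}" for k in range(config.n_groups)]
    levels = np.linspace(config.n_levels, 1, config.n_levels)
    group_scores = {g: float(levels[k % config.n_levels]) for k, g in enumerate(groups)}
    sample_groups = {}
    sample_names = base.peaks.samples
    for k, g in enumerate(groups):
        for r in range(config.replicates):
            sample_groups[sample_names[k * config.replicates + r]] = g
    design = PhenotypeDesign(sample_groups, group_scores)

    scores = np.array([group_scores[sample_groups[s]] for s in sample_names])
    z = (scores - scores.mean()) / scores.std()

    candidates = base.truth.loc[
        base.truth["kind"].isin(["peptide", "chain"]), "peak_id"
    ].tolist()
    n_spike = int(round(config.spiked_fraction * len(candidates)))
    spiked = sorted(rng.choice(candidates, size=n_spike, replace=False).tolist())

    mat = base.peaks.intensities.copy()
    for pid in spiked:
        mat.loc[pid] = mat.loc[pid].to_numpy() * np.exp(config.effect_size * z)

    peaks = PeakList(
        list(base.peaks.ids), base.peaks.masses.copy(), mat.reset_index(drop=True),
        base.peaks.polarity,
    )
    truth = base.truth.copy()
    truth["spiked"] = truth["peak_id"].isin(spiked)
    logger.info(
        "phenotype simulation: %d groups x %d replicates, %d spiked feature(s)",
        config.n_groups,
        config.replicates,
        len(spiked),
    )
    return PhenotypeSimulation(peaks, design, truth, config)
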