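"""Seeded generators for every input the pipeline consumes.

Ground truth is explicit: antibody position preferences drive simulated
array signals, planted site catalogs with controlled novelty feed the
methylome analytics, and a capture model with tunable PSSM bias emulates
antibody enrichment ahead of the PSM table.  Every generator is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .array_processing import ArrayScan
from .kopl_design import AA20, FLANK_OFFSETS, KoplLibrary, MethylState
from .methylome_catalog import Mod, PeptideRecord, ReferenceCatalog
from .selectivity_metrics import Pssm, extract_window, score_7mer


@dataclass
class TruthAntibody:
    """Ground-truth binding model for one simulated antibody.

    Expected array signal for a library set fixing ``aa`` at ``offset`` on a
    library of state ``s`` is
    ``global_intensity * cross_reactivity[s] * preference[(offset, aa)]``.
    """

    antibody_id: str
    target_state: MethylState
    preference: dict[tuple[int, str], float]
    cross_reactivity: dict[MethylState, float] = field(default_factory=dict)
    global_intensity: float = 1000.0

    def __post_init__(self) -> None:
        self.target_state = MethylState(self.target_state)
        self.cross_reactivity = {
            MethylState(k): float(v) for k, v in self.cross_reactivity.items()
        }
        self.cross_reactivity.setdefault(self.target_state, 1.0)
        if self.cross_reactivity[self.target_state] != 1.0:
            raise ValueError("cross_reactivity of the target state must be 1")
        if not any(w > 0 for w in self.preference.values()):
            raise ValueError("at least one preference weight must be positive")
        if any(w < 0 for w in self.preference.values()):
            raise ValueError("preference weights must be >= 0")
        if not self.global_intensity > 0:
            raise ValueError("global_intensity must be > 0")

    @classmethod
    def uniform(cls, antibody_id: str, target_state: MethylState,
                weight: float = 1.0, **kw) -> "TruthAntibody":
        """A perfectly pan antibody: every (offset, aa) weight equal."""
        from .kopl_design import AA19
        pref = {(off, aa): weight for off in FLANK_OFFSETS for aa in AA19}
        return cls(antibody_id, target_state, pref, **kw)

    @classmethod
    def biased(cls, antibody_id: str, target_state: MethylState,
               favored: Mapping[tuple[int, str], float],
               base_weight: float = 0.05, **kw) -> "TruthAntibody":
        """Uniform base binding plus elevated weights at ``favored`` cells."""
        ab = cls.uniform(antibody_id, target_state, weight=base_weight, **kw)
        for cell, w in favored.items():
            if cell not in ab.preference:
                raise KeyError(f"favored cell {cell} is not a library cell")
            ab.preference[cell] = float(w)
        return ab


#: Roughly human-like amino-acid composition (normalized at use).
DEFAULT_COMPOSITION = {
    "A": 7.0, "C": 2.3, "D": 4.7, "E": 7.1, "F": 3.7, "G": 6.6, "H": 2.6,
    "I": 4.3, "K": 5.7, "L": 10.0, "M": 2.1, "N": 3.6, "P": 6.3, "Q": 4.8,
    "R": 5.6, "S": 8.3, "T": 5.3, "V": 6.0, "W": 1.2, "Y": 2.7,
}


@dataclass
class SimConfig:
    """Knobs for all generators.  Rates are probabilities in [0, 1]."""

    seed: int = 0
    n_proteins: int = 50
    mean_length: int = 300
    min_length: int = 30
    aa_composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION))
    noise_cv: float = 0.2
    n_replicates: int = 3
    site_rates: dict[str, float] = field(
        default_factory=lambda: {"me1": 0.03, "me2": 0.03, "me3": 0.03})
    reference_fraction: float = 0.4
    enrichment_bias_strength: float = 0.0
    capture_rate: float = 1.0
    unenriched_rate: float = 0.1
    localization_jitter: float = 0.0
    decoy_mod_rate: float = 0.0
    phospho_cooccurrence_rate: float = 0.0
    partial_me2_cleavage: float = 0.0
    crosstalk_planting: dict[str, tuple[Sequence[int], float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        comp = np.array([self.aa_composition.get(a, 0.0) for a in AA20], dtype=float)
        if (comp < 0).any() or comp.sum() <= 0:
            raise ValueError("aa_composition must be non-negative with positive mass")
        comp = comp / comp.sum()
        self.aa_composition = {a: float(f) for a, f in zip(AA20, comp)}
        for name in ("reference_fraction", "capture_rate", "unenriched_rate",
                     "localization_jitter", "decoy_mod_rate",
                     "phospho_cooccurrence_rate", "partial_me2_cleavage"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for state, rate in self.site_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"site rate for {state} must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "crosstalk_planting" in data:
            data["crosstalk_planting"] = {
                k: (tuple(v[0]), float(v[1]))
                for k, v in data["crosstalk_planting"].items()
            }
        return cls(**data)

    def composition_vector(self) -> np.ndarray:
        return np.array([self.aa_composition[a] for a in AA20])


def _rng(cfg_or_seed, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    seed = cfg_or_seed.seed if isinstance(cfg_or_seed, SimConfig) else cfg_or_seed
    return np.random.default_rng(seed)


def gen_proteome(cfg: SimConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Seeded synthetic protein set with accessions ``SYN0001``.. ."""
    rng = _rng(cfg, rng)
    comp = cfg.composition_vector()
    letters = np.array(list(AA20))
    proteome: dict[str, str] = {}
    for i in range(cfg.n_proteins):
        length = max(cfg.min_length, int(rng.poisson(cfg.mean_length)))
        seq = "".join(rng.choice(letters, size=length, p=comp))
        proteome[f"SYN{i + 1:04d}"] = seq
    return proteome


def write_fasta(proteome: Mapping[str, str], path, width: int = 60) -> None:
    """Deterministic plain FASTA writer (byte-identical across runs)."""
    with open(path, "w") as fh:
        for acc in proteome:
            fh.write(f">{acc}\n")
            seq = proteome[acc]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def sim_kopl_array(truth: TruthAntibody, library: KoplLibrary, cfg: SimConfig,
                   rng: np.random.Generator | None = None) -> ArrayScan:
    """Simulated replicate scan of one library by one antibody.

    Replicate noise is multiplicative lognormal with coefficient of variation
    ``cfg.noise_cv`` and unit mean; ``noise_cv = 0`` gives exact expected
    signals.
    """
    rng = _rng(cfg, rng)
    cross = truth.cross_reactivity.get(library.state, 0.0)
    if cfg.noise_cv > 0:
        sigma = float(np.sqrt(np.log(1.0 + cfg.noise_cv ** 2)))
        mu = -0.5 * sigma ** 2  # unit-mean lognormal
    rows = []
    for s in library.sets:
        expected = truth.global_intensity * cross * truth.preference.get(
            (s.fixed_offset, s.fixed_aa), 0.0)
        for rep in range(1, cfg.n_replicates + 1):
            signal = expected
            if cfg.noise_cv > 0 and expected > 0:
                signal = expected * float(rng.lognormal(mu, sigma))
            rows.append((s.set_id, rep, signal))
    records = pd.DataFrame(rows, columns=["feature_id", "replicate", "raw_signal"])
    return ArrayScan(antibody_id=truth.antibody_id, records=records,
                     n_replicates=cfg.n_replicates)


@dataclass
class SimMethylome:
    """Planted site catalog plus the reference split derived from it."""

    sites: pd.DataFrame  # accession, position, state, in_reference
    reference: ReferenceCatalog

    def site_tuples(self) -> list[tuple[str, int, str]]:
        return list(zip(self.sites["accession"], self.sites["position"],
                        self.sites["state"]))


def sim_methylome(proteome: Mapping[str, str], cfg: SimConfig,
                  motif_bias: Pssm | None = None,
                  rng: np.random.Generator | None = None) -> SimMethylome:
    """Plant methyl sites on proteome lysines, with optional motif structure.

    Per state, the number of sites is binomial in the lysine count at the
    configured rate; with ``motif_bias`` the sampled lysines are weighted by
    ``exp(score)`` so motif enrichment is recoverable downstream.  A
    ``cfg.reference_fraction`` of planted sites is copied into the reference
    catalog (controlling true novelty), and crosstalk PTMs are planted around
    methyl sites at the configured offsets and rates.
    """
    rng = _rng(cfg, rng)
    lysines = [
        (acc, i + 1)
        for acc in proteome
        for i, res in enumerate(proteome[acc])
        if res == "K"
    ]
    weights = np.ones(len(lysines))
    if motif_bias is not None and lysines:
        scores = np.array([
            score_7mer(motif_bias, extract_window(proteome[acc], pos, pad=True))
            for acc, pos in lysines
        ])
        weights = np.exp(scores - scores.max())
    taken: set[tuple[str, int]] = set()
    site_rows = []
    ref_rows = []
    for state in sorted(cfg.site_rates):
        rate = cfg.site_rates[state]
        free = [i for i, key in enumerate(lysines) if key not in taken]
        if not free or rate == 0:
            continue
        n_pick = int(rng.binomial(len(free), rate))
        if n_pick == 0:
            continue
        w = weights[free]
        picked = rng.choice(len(free), size=n_pick, replace=False, p=w / w.sum())
        for j in sorted(picked):
            acc, pos = lysines[free[j]]
            taken.add((acc, pos))
            in_ref = bool(rng.random() < cfg.reference_fraction)
            site_rows.append((acc, pos, state, in_ref))
            if in_ref:
                ref_rows.append((acc, pos, state))
            for ptm_type, (offsets, ptm_rate) in sorted(cfg.crosstalk_planting.items()):
                if rng.random() < ptm_rate:
                    off = int(rng.choice(np.asarray(offsets)))
                    target = pos + off
                    if 1 <= target <= len(proteome[acc]):
                        ref_rows.append((acc, target, ptm_type))
    sites = pd.DataFrame(site_rows,
                         columns=["accession", "position", "state", "in_reference"])
    sites = sites.sort_values(["accession", "position", "state"]).reset_index(drop=True)
    reference = ReferenceCatalog(pd.DataFrame(
        ref_rows, columns=["accession", "position", "ptm_type"]))
    return SimMethylome(sites=sites, reference=reference)


def tryptic_peptides(sequence: str, blocked_positions: frozenset[int] = frozenset(),
                     ) -> list[tuple[int, str]]:
    """Tryptic-style digest: cleave after K/R unless the K is blocked.

    ``blocked_positions`` are 1-based positions of lysines (e.g. methylated)
    that do not cleave.  Returns (1-based start, peptide) pairs.
    """
    cuts = [0]
    for i, res in enumerate(sequence):
        if res == "R" or (res == "K" and (i + 1) not in blocked_positions):
            cuts.append(i + 1)
    if cuts[-1] != len(sequence):
        cuts.append(len(sequence))
    return [(a + 1, sequence[a:b]) for a, b in zip(cuts[:-1], cuts[1:]) if b > a]


@dataclass
class StrategySpec:
    """One enrichment strategy in the PSM simulation."""

    label: str
    n_runs: int = 1
    capture_rate: float = 1.0
    bias_strength: float = 0.0  # logistic weighting by the capture PSSM score


def _capture_probability(z: float, capture_rate: float, bias_strength: float) -> float:
    """min(1, rate * 2 * sigmoid(bias * z)) — equals ``rate`` when unbiased."""
    logistic = 1.0 / (1.0 + np.exp(-bias_strength * z))
    return float(min(1.0, capture_rate * 2.0 * logistic))


def sim_psm_table(methylome: SimMethylome, proteome: Mapping[str, str],
                  cfg: SimConfig, capture_pssm: Pssm | None = None,
                  strategies: Sequence[StrategySpec] | None = None,
                  rng: np.random.Generator | None = None) -> list[PeptideRecord]:
    """Simulate a PSM table from the planted site catalog.

    Proteins are digested tryptic-style with methylated lysines blocking
    cleavage (optionally leaky for me2).  Each strategy captures each site
    independently at a probability that is logistic in the (standardized)
    capture-PSSM score of the site window, scaled by the strategy's bias
    strength; unbiased strategies capture at their flat rate.  Localization
    probabilities are 1 minus a uniform jitter for true sites; decoy methyl
    mods (if enabled) carry low probabilities.
    """
    rng = _rng(cfg, rng)
    if strategies is None:
        strategies = [
            StrategySpec("enriched", capture_rate=cfg.capture_rate,
                         bias_strength=cfg.enrichment_bias_strength),
            StrategySpec("unenriched", capture_rate=cfg.unenriched_rate),
        ]
    sites = methylome.sites
    blocked_by_acc: dict[str, set[int]] = {}
    for acc, pos, state in methylome.site_tuples():
        if state == "me2" and cfg.partial_me2_cleavage > 0 and \
                rng.random() < cfg.partial_me2_cleavage:
            continue  # leaky cleavage: this di-methyl K behaves like free K
        blocked_by_acc.setdefault(acc, set()).add(int(pos))
    digests = {
        acc: tryptic_peptides(proteome[acc],
                              frozenset(blocked_by_acc.get(acc, set())))
        for acc in sorted({a for a in sites["accession"]})
    }

    if capture_pssm is not None and len(sites):
        raw = np.array([
            score_7mer(capture_pssm, extract_window(proteome[acc], int(pos), pad=True))
            for acc, pos in zip(sites["accession"], sites["position"])
        ])
        spread = raw.std()
        zscores = (raw - raw.mean()) / spread if spread > 0 else np.zeros(len(raw))
    else:
        zscores = np.zeros(len(sites))

    records: list[PeptideRecord] = []
    for spec in strategies:
        for run in range(1, spec.n_runs + 1):
            run_label = f"{spec.label}-R{run}"
            for idx in range(len(sites)):
                acc = sites.at[idx, "accession"]
                pos = int(sites.at[idx, "position"])
                state = sites.at[idx, "state"]
                p = _capture_probability(float(zscores[idx]), spec.capture_rate,
                                         spec.bias_strength)
                if rng.random() >= p:
                    continue
                peptide = _peptide_containing(digests[acc], pos)
                if peptide is None:
                    continue  # cleaved-through me2 site: not recoverable
                start, seq = peptide
                mods = [Mod(residue_index=pos - start + 1, type=state,
                            localization_probability=_loc_prob(cfg, rng))]
                if cfg.phospho_cooccurrence_rate > 0 and \
                        rng.random() < cfg.phospho_cooccurrence_rate:
                    sty = [i + 1 for i, r in enumerate(seq) if r in "STY"]
                    if sty:
                        i = int(rng.choice(sty))
                        mods.append(Mod(residue_index=i, type=f"phospho-{seq[i - 1]}",
                                        localization_probability=_loc_prob(cfg, rng)))
                if cfg.decoy_mod_rate > 0 and rng.random() < cfg.decoy_mod_rate:
                    ks = [i + 1 for i, r in enumerate(seq)
                          if r == "K" and (start + i) != pos]
                    if ks:
                        i = int(rng.choice(ks))
                        mods.append(Mod(residue_index=i,
                                        type=str(rng.choice(["me1", "me2", "me3"])),
                                        localization_probability=float(rng.uniform(0.0, 0.5))))
                records.append(PeptideRecord(
                    sequence=seq, mods=tuple(mods), accession=acc,
                    protein_start=start, run_label=run_label,
                    strategy_label=spec.label, is_psm=True,
                ))
    return records


def _loc_prob(cfg: SimConfig, rng: np.random.Generator) -> float:
    if cfg.localization_jitter == 0:
        return 1.0
    return float(1.0 - rng.uniform(0.0, cfg.localization_jitter))


def _peptide_containing(digest: list[tuple[int, str]], position: int):
    for start, seq in digest:
        if start <= position < start + len(seq):
            return start, seq
    return None
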