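"""Synthetic sequence and assay data with known ground truth.

Every pipeline stage can be exercised without wet-lab data: coding-sequence
pairs diverged under a controllable dN/dS, single-concentration screens
over an odor panel with triplicate noise and occasional inhibitory odors,
3-parameter-logistic dose-response plates with known EC50 and span, and
Gaussian-blob descriptor matrices standing in for the real chemical space.
All generators are pure functions of their configuration (seed included).

The sequence simulator uses an acceptance-probability scheme rather than a
full codon rate matrix: proposed point mutations are accepted with
probability 1 if synonymous and probability omega if nonsynonymous
(mutations creating stop codons are always rejected). At desk scale this
targets the realized dN/dS directly and is easy to audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dose_response import DoseResponseDataset, logistic3
from .seq_evol import (
    CODON_TABLE,
    SENSE_CODONS,
    STOP_CODONS,
    NUCLEOTIDES,
    CodingSequencePair,
)

# Default concentration design: seven log-spaced points, 10 nM to 10 mM.
DEFAULT_LOG_CONC = np.arange(-8.0, -1.0)


@dataclass(frozen=True)
class SequenceSimConfig:
    """Ortholog-pair divergence simulation settings.

    ``expected_substitutions`` is the Poisson mean of accepted substitutions
    per branch (two independent branches from the ancestor). ``omega`` is
    the target dN/dS; values above 1 are realized by down-weighting
    synonymous acceptance to 1/omega instead. ``ts_tv`` weights transition
    proposals relative to each transversion (1 = uniform).
    """

    n_codons: int = 300
    expected_substitutions: float = 30.0
    omega: float = 0.3
    ts_tv: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_codons < 30:
            raise ValueError("need >= 30 codons for stable dN/dS estimates")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class SimulatedOrthologPair:
    pair: CodingSequencePair
    n_synonymous: int     # accepted synonymous substitutions, both branches
    n_nonsynonymous: int


def _random_orf(rng: np.random.Generator, n_codons: int) -> list[str]:
    codons = ["ATG"]
    choices = rng.choice(len(SENSE_CODONS), size=n_codons - 1)
    codons += [SENSE_CODONS[i] for i in choices]
    return codons


def _evolve_branch(
    rng: np.random.Generator, codons: list[str], cfg: SequenceSimConfig
) -> tuple[list[str], int, int]:
    codons = list(codons)
    n_target = rng.poisson(cfg.expected_substitutions)
    if cfg.omega <= 1.0:
        p_syn, p_nonsyn = 1.0, cfg.omega
    else:
        p_syn, p_nonsyn = 1.0 / cfg.omega, 1.0
    n_syn = n_nonsyn = 0
    accepted = 0
    guard = 0
    max_proposals = max(1000, 2000 * n_target)
    while accepted < n_target and guard < max_proposals:
        guard += 1
        site = int(rng.integers(0, 3 * len(codons)))
        ci, pos = divmod(site, 3)
        codon = codons[ci]
        base = codon[pos]
        others = [b for b in NUCLEOTIDES if b != base]
        w = np.array([cfg.ts_tv if b == _TRANSITION[base] else 1.0 for b in others])
        alt = others[int(rng.choice(3, p=w / w.sum()))]
        mutant = codon[:pos] + alt + codon[pos + 1 :]
        if mutant in STOP_CODONS:
            continue
        synonymous = CODON_TABLE[mutant] == CODON_TABLE[codon]
        p_accept = p_syn if synonymous else p_nonsyn
        if rng.random() < p_accept:
            codons[ci] = mutant
            accepted += 1
            if synonymous:
                n_syn += 1
            else:
                n_nonsyn += 1
    return codons, n_syn, n_nonsyn


def simulate_ortholog_pair(cfg: SequenceSimConfig) -> SimulatedOrthologPair:
    """Evolve two descendants of a random stop-free ORF; record realized counts."""
    rng = np.random.default_rng(cfg.seed)
    ancestor = _random_orf(rng, cfg.n_codons)
    a, sa, na = _evolve_branch(rng, ancestor, cfg)
    b, sb, nb = _evolve_branch(rng, ancestor, cfg)
    pair = CodingSequencePair.from_nucleotides("ortholog_a", "".join(a),
                                               "ortholog_b", "".join(b))
    return SimulatedOrthologPair(pair, sa + sb, na + nb)


# ---------------------------------------------------------------------------
# Assay simulators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssaySimConfig:
    """Shared settings for the dose-response and screen simulators.

    ``curve_params`` maps receptor -> (bottom, top, logEC50) in response
    units / log10 molar. ``screen_effects`` maps receptor -> per-odor
    normalized effect sizes (negative = inhibitory). Noise is Gaussian and
    homoscedastic with SD expressed as a fraction of the span (log-normal
    multiplicative noise available via noise_model="lognormal").
    """

    curve_params: dict = field(default_factory=dict)
    log_concentrations: tuple = tuple(DEFAULT_LOG_CONC)
    n_replicates: int = 3
    noise_sd: float = 0.05
    noise_model: str = "normal"
    screen_effects: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be > 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.noise_model not in ("normal", "lognormal"):
            raise ValueError("noise_model must be 'normal' or 'lognormal'")


def _add_noise(rng, clean: np.ndarray, sd: float, model: str) -> np.ndarray:
    if model == "normal":
        return clean + rng.normal(0.0, sd, size=clean.shape)
    return clean * rng.lognormal(0.0, sd, size=clean.shape)


def simulate_dose_response(
    cfg: AssaySimConfig, odor: str = "odor1"
) -> tuple[dict[str, DoseResponseDataset], DoseResponseDataset]:
    """Generate triplicated 3PL responses per receptor plus a vector control.

    The control is flat at the smallest configured bottom plus noise. Noise
    SD is ``noise_sd`` times each receptor's span (the control uses the
    largest configured span as its scale so its noise is comparable).
    """
    rng = np.random.default_rng(cfg.seed)
    x = np.asarray(cfg.log_concentrations, dtype=float)
    conc = 10.0 ** x
    datasets = {}
    spans = []
    bottoms = []
    for receptor, (bottom, top, logec50) in cfg.curve_params.items():
        span = top - bottom
        spans.append(abs(span))
        bottoms.append(bottom)
        clean = logistic3(x, bottom, top, logec50)[:, None]
        clean = np.repeat(clean, cfg.n_replicates, axis=1)
        noisy = _add_noise(rng, clean, cfg.noise_sd * abs(span), cfg.noise_model)
        datasets[receptor] = DoseResponseDataset(receptor, odor, conc, noisy)
    scale = max(spans) if spans else 1.0
    base = min(bottoms) if bottoms else 0.0
    ctrl_clean = np.full((x.size, cfg.n_replicates), base)
    ctrl = _add_noise(rng, ctrl_clean, cfg.noise_sd * scale, cfg.noise_model)
    control = DoseResponseDataset("vector", odor, conc, ctrl)
    return datasets, control


def simulate_screen(cfg: AssaySimConfig, n_odors: int = 42,
                    odors: list[str] | None = None) -> pd.DataFrame:
    """Generate a plate table for a single-concentration odor screen.

    Per receptor, each odor's firefly/Renilla ratio is a baseline plus the
    configured effect plus noise; no-odor and vector-control wells are
    included. Renilla values are jittered around a common level so the
    ratio normalization has something to correct.
    """
    rng = np.random.default_rng(cfg.seed)
    odors = odors or [f"odor{i + 1:02d}" for i in range(n_odors)]
    baseline = 1.0
    rows = []
    receptors = list(cfg.screen_effects) or ["OR_sim"]
    for receptor in receptors:
        effects = np.zeros(len(odors))
        configured = cfg.screen_effects.get(receptor, {})
        for i, odor in enumerate(odors):
            effects[i] = configured.get(odor, 0.0)
        for odor, eff in [(o, e) for o, e in zip(odors, effects)] + [
            ("no_odor", 0.0), ("vector", 0.0)
        ]:
            for rep in range(1, cfg.n_replicates + 1):
                renilla = rng.normal(1000.0, 30.0)
                ratio = baseline + eff + rng.normal(0.0, cfg.noise_sd)
                rows.append({
                    "receptor": receptor,
                    "odor": odor,
                    "replicate": rep,
                    "firefly": ratio * renilla,
                    "renilla": renilla,
                    "plate_id": f"{receptor}_plate",
                })
    return pd.DataFrame(rows)


def simulate_descriptor_space(n: int = 500, d: int = 20, n_blobs: int = 10,
                              seed: int = 0, separation: float = 8.0,
                              active_fraction: float = 0.15):
    """Gaussian-blob descriptor matrix with random known-active flags."""
    from sklearn.datasets import make_blobs

    from .odor_space import DescriptorMatrix

    X, _ = make_blobs(n_samples=n, n_features=d, centers=n_blobs,
                      cluster_std=1.0, center_box=(-separation, separation),
                      random_state=seed)
    rng = np.random.default_rng(seed)
    active = rng.random(n) < active_fraction
    ids = tuple(f"odorant{i + 1:04d}" for i in range(n))
    return DescriptorMatrix(ids, X, active)


# ---------------------------------------------------------------------------
# End-to-end synthetic study
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudySimConfig:
    """A small synthetic comparative study with linked sequence and function.

    ``n_sets`` ortholog pairs are simulated with per-pair divergence and
    omega drawn from the configured grids; each variant's screen profile is
    the reference profile plus Gaussian perturbation whose SD grows with the
    pair's realized amino-acid divergence (``func_coupling`` response units
    per accepted nonsynonymous substitution). Because the perturbation
    follows protein (not nucleotide) divergence, amino-acid-aware sequence
    metrics should track functional distance more closely than purely
    nucleotide ones.
    """

    n_sets: int = 12
    n_codons: int = 300
    substitution_grid: tuple = (6.0, 12.0, 24.0, 48.0)
    omega_grid: tuple = (0.05, 0.3, 0.9)
    func_coupling: float = 0.03
    n_odors: int = 42
    n_responsive: int = 8
    effect_size: float = 1.0
    inhibitory_fraction: float = 0.1
    noise_sd: float = 0.05
    n_replicates: int = 3
    seed: int = 0


@dataclass(frozen=True)
class SyntheticStudy:
    pairs: list[SimulatedOrthologPair]
    plate: pd.DataFrame              # screen wells for all receptors
    pair_table: pd.DataFrame         # id_a, id_b, true divergence bookkeeping


def simulate_study(cfg: StudySimConfig) -> SyntheticStudy:
    rng = np.random.default_rng(cfg.seed)
    pairs = []
    records = []
    effects_by_receptor: dict[str, dict[str, float]] = {}
    odors = [f"odor{i + 1:02d}" for i in range(cfg.n_odors)]

    for s in range(cfg.n_sets):
        subs = cfg.substitution_grid[s % len(cfg.substitution_grid)]
        omega = cfg.omega_grid[(s // len(cfg.substitution_grid)) % len(cfg.omega_grid)]
        seq_cfg = SequenceSimConfig(
            n_codons=cfg.n_codons, expected_substitutions=subs,
            omega=omega, seed=int(rng.integers(0, 2**31 - 1)),
        )
        sim = simulate_ortholog_pair(seq_cfg)
        ref_id, var_id = f"set{s:02d}_ref", f"set{s:02d}_var"
        pair = replace(sim.pair, id_a=ref_id, id_b=var_id)
        sim = SimulatedOrthologPair(pair, sim.n_synonymous, sim.n_nonsynonymous)
        pairs.append(sim)

        # reference tuning profile: a handful of agonists, some inhibitory
        profile = np.zeros(cfg.n_odors)
        responsive = rng.choice(cfg.n_odors, size=cfg.n_responsive, replace=False)
        for idx in responsive:
            mag = cfg.effect_size * rng.uniform(0.4, 1.0)
            if rng.random() < cfg.inhibitory_fraction:
                mag = -mag
            profile[idx] = mag
        perturb_sd = cfg.func_coupling * sim.n_nonsynonymous
        variant = profile + rng.normal(0.0, perturb_sd, size=cfg.n_odors)

        effects_by_receptor[ref_id] = dict(zip(odors, profile))
        effects_by_receptor[var_id] = dict(zip(odors, variant))
        records.append({
            "id_a": ref_id, "id_b": var_id,
            "expected_substitutions": subs, "target_omega": omega,
            "realized_syn": sim.n_synonymous, "realized_nonsyn": sim.n_nonsynonymous,
            "perturb_sd": perturb_sd,
        })

    assay_cfg = AssaySimConfig(
        screen_effects=effects_by_receptor, noise_sd=cfg.noise_sd,
        n_replicates=cfg.n_replicates, seed=int(rng.integers(0, 2**31 - 1)),
    )
    plate = simulate_screen(assay_cfg, n_odors=cfg.n_odors, odors=odors)
    return SyntheticStudy(pairs, plate, pd.DataFrame(records))
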