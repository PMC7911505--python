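"""Ground-truth cohort simulator for targeted bisulfite amplicon studies.

Emulates a two-tissue (brain/gut), two-group (CTRL/PROBIO) zebrafish
cohort of five fish per group sequenced with 251x2 paired-end chemistry:
a Tph1A-like promoter amplicon (318 bp, 11 CpGs, intermediate methylation,
BS and oxBS libraries), a BDNF-like promoter amplicon (417 bp, 21 CpGs,
near-zero methylation), an unmethylated spike-in conversion control, and
behavioral scores (DV, OA, CP) linearly coupled to an epiallele-class
frequency.

Molecules are drawn from per-fish epiallele models: a mixture of epitype
patterns with site-flip noise (subpopulations of cells sharing a
methylation configuration) or site-independent Bernoulli methylation for
the low-methylation amplicon. Reads carry incomplete-conversion,
over-conversion and sequencing-error noise. All randomness flows from one
seed.

Default group means and between-fish spreads encode the study conditions
this generator emulates (gut CTRL 70.38 +/- 4 %, brain CTRL 51.24 +/- 0.8 %,
gut PROBIO 62.1 +/- 1.4 %, brain PROBIO 53.2 +/- 2.1 %; BDNF-like gut
0.72 +/- 0.06 %, brain 0.41 +/- 0.034 %; means as group average, spreads as
the standard error over five fish).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .amplicon import AmpliconSpec, revcomp
from .reads import FastqRead

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


# ---------------------------------------------------------------------------
# amplicon construction

def make_amplicon(n_cpg: int, length: int, seed, name: str = "amplicon",
                  min_noncpg_c: int = 15, tss_frac: float = 0.62) -> AmpliconSpec:
    """Random amplicon with exactly ``n_cpg`` CpGs and no accidental extras.

    Guarantees at least ``min_noncpg_c`` cytosines outside CpG context so
    per-read conversion efficiency is measurable. The TSS sits at
    ``tss_frac`` of the length, giving promoter-style coordinates spanning
    negative and positive values.
    """
    if n_cpg > length // 2:
        raise ValueError(f"cannot place {n_cpg} CpGs in {length} bp")
    if length < 4:
        raise ValueError("amplicon too short")
    rng = np.random.default_rng(seed)
    # background without C or G avoids any unintended CpG; C and G are
    # reintroduced in controlled contexts below
    seq = rng.choice(np.frombuffer(b"AT", dtype=np.uint8), size=length)
    # CpG sites: starts on an even grid away from the edges, so any two
    # chosen sites are >= 2 apart and CG dinucleotides cannot collide
    grid = np.arange(2, length - 2, 2)
    if len(grid) < n_cpg:
        raise ValueError(f"cannot place {n_cpg} CpGs in {length} bp")
    starts = np.sort(rng.choice(grid, size=n_cpg, replace=False))
    for s in starts:
        seq[s], seq[s + 1] = ord("C"), ord("G")
    # sprinkle non-CpG cytosines and guanines at safe positions
    cpg_zone = set()
    for s in starts:
        cpg_zone.update((s - 1, s, s + 1))
    free = [i for i in range(length - 1) if i not in cpg_zone
            and i + 1 not in cpg_zone]
    rng.shuffle(free)
    n_extra_c = max(min_noncpg_c, int(0.15 * length))
    placed_c = 0
    for i in free:
        if placed_c >= n_extra_c:
            break
        if seq[i + 1] != ord("G") and (i == 0 or seq[i - 1] != ord("C")):
            seq[i] = ord("C")
            placed_c += 1
    for i in free[len(free) // 2:]:
        if seq[i] in (ord("A"), ord("T")) and (i == 0 or seq[i - 1] != ord("C")) \
                and rng.random() < 0.3:
            seq[i] = ord("G")
    sequence = seq.tobytes().decode("ascii")
    spec = AmpliconSpec(name=name, sequence=sequence,
                        tss_index=int(length * tss_frac))
    if spec.n_cpg != n_cpg:
        raise RuntimeError(
            f"amplicon construction produced {spec.n_cpg} CpGs, wanted {n_cpg}")
    if len(spec.noncpg_c_indices) < min_noncpg_c:
        raise RuntimeError("too few non-CpG cytosines for QC")
    return spec


# ---------------------------------------------------------------------------
# epiallele models

@dataclass(frozen=True)
class IndependentModel:
    """Site-independent Bernoulli methylation with per-CpG probabilities."""

    p: np.ndarray

    @property
    def n_cpg(self) -> int:
        return len(self.p)

    def site_prob_rows(self):
        """(weight, per-site methylation probability) components."""
        return [(1.0, np.asarray(self.p, dtype=float))]


@dataclass(frozen=True)
class MixtureModel:
    """Mixture of epitype patterns with per-site flip noise.

    Each molecule descends from one epitype (a cell subpopulation's
    methylation configuration) drawn by weight; every site then flips with
    probability ``flip_rate``, modelling within-subpopulation scatter.
    """

    epitypes: np.ndarray          # (E, N) 0/1
    weights: np.ndarray           # (E,), sums to 1
    flip_rate: float = 0.0

    def __post_init__(self):
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if not 0 <= self.flip_rate <= 1:
            raise ValueError("flip_rate outside [0, 1]")

    @property
    def n_cpg(self) -> int:
        return self.epitypes.shape[1]

    def site_prob_rows(self):
        e = self.flip_rate
        probs = self.epitypes * (1 - e) + (1 - self.epitypes) * e
        return [(float(w), probs[i]) for i, w in enumerate(self.weights)]


def _site_observation_prob(probs: np.ndarray, hmc_fraction: float,
                           noise: "NoiseModel | None") -> np.ndarray:
    """Probability a CpG site reads methylated, per site.

    Chains the chemistry: a methylated site escapes oxBS-style conversion
    with probability (1 - hmc_fraction), survives over-conversion, and an
    unmethylated site can fail to convert (incomplete conversion).
    """
    q = probs * (1.0 - hmc_fraction)
    if noise is None:
        return q
    return (q * (1.0 - noise.over_conversion)
            + (1.0 - q) * noise.incomplete_conversion)


def expected_per_cpg_p(model, hmc_fraction: float = 0.0,
                       noise: "NoiseModel | None" = None) -> np.ndarray:
    """Exact per-CpG probability of reading methylated.

    With oxidative-bisulfite chemistry a methylated site is 5hmC with
    probability ``hmc_fraction`` and then reads unmethylated. Passing the
    noise model additionally folds in incomplete and over-conversion,
    giving the expectation of what the pipeline *observes*.
    """
    p = np.zeros(model.n_cpg)
    for w, probs in model.site_prob_rows():
        p += w * _site_observation_prob(probs, hmc_fraction, noise)
    return p


def poisson_binomial(probs: np.ndarray) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_j): length N+1."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def expected_class_freqs(model, hmc_fraction: float = 0.0,
                         noise: "NoiseModel | None" = None) -> np.ndarray:
    """Exact epiallele-class distribution (classes 0..N) under the model.

    Each mixture component's class count is Poisson-binomial over its
    per-site observation probabilities; with ``noise`` given, conversion
    errors are folded in (observed distribution rather than biological).
    """
    out = np.zeros(model.n_cpg + 1)
    for w, probs in model.site_prob_rows():
        out += w * poisson_binomial(
            _site_observation_prob(probs, hmc_fraction, noise))
    return out


def sample_epialleles(model, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n molecules as a (n, N) 0/1 pattern matrix."""
    if isinstance(model, IndependentModel):
        return (rng.random((n, model.n_cpg)) < model.p).astype(np.int8)
    idx = rng.choice(len(model.weights), size=n, p=model.weights)
    pats = model.epitypes[idx].astype(np.int8)
    if model.flip_rate > 0:
        flips = rng.random(pats.shape) < model.flip_rate
        pats = np.where(flips, 1 - pats, pats)
    return pats


def patterns_to_strings(patterns: np.ndarray) -> list[str]:
    return ["".join(map(str, row)) for row in patterns]


# ---------------------------------------------------------------------------
# read emission

@dataclass(frozen=True)
class NoiseModel:
    """Chemistry and sequencing noise rates (per site / per base)."""

    incomplete_conversion: float = 0.002  # unmethylated C left as C
    over_conversion: float = 0.005        # methylated C read as T
    seq_error: float = 0.002              # per-base miscall, uniform
    hmc_fraction: float = 0.02            # methylated sites that are 5hmC


_QUAL_CHARS = np.frombuffer(b"I5#", dtype=np.uint8)   # Q40 / Q20 / Q2
_QUAL_PROBS = (0.92, 0.06, 0.02)


def emit_reads(
    patterns: np.ndarray,
    spec: AmpliconSpec,
    noise: NoiseModel,
    chemistry: str,
    rng: np.random.Generator,
    read_len: int = 251,
    id_prefix: str = "mol",
) -> list[tuple[FastqRead, FastqRead]]:
    """Turn pattern matrix into noisy 251x2-style read pairs.

    Per molecule: methylated CpGs stay C (unless over-converted, or 5hmC
    under oxBS chemistry), every other C reads T (unless conversion was
    incomplete), uniform sequencing errors are layered on, and the
    molecule is split into two overlapping mates (mate 2 reverse-
    complemented), guaranteeing overlap because the amplicon is shorter
    than twice the read length.
    """
    if chemistry not in ("BS", "oxBS"):
        raise ValueError(f"unknown chemistry {chemistry!r}")
    n, n_cpg = patterns.shape
    if n_cpg != spec.n_cpg:
        raise ValueError("pattern width does not match amplicon CpG count")
    L = spec.length_bp
    mol = np.tile(np.frombuffer(spec.sequence.encode(), np.uint8), (n, 1))

    meth = patterns.astype(bool)
    if chemistry == "oxBS" and noise.hmc_fraction > 0:
        hm = meth & (rng.random((n, n_cpg)) < noise.hmc_fraction)
        protected = meth & ~hm
    else:
        protected = meth
    reads_c = np.where(
        protected,
        rng.random((n, n_cpg)) >= noise.over_conversion,
        rng.random((n, n_cpg)) < noise.incomplete_conversion,
    )
    cpg_idx = np.array(spec.cpg_indices, dtype=int)
    mol[:, cpg_idx] = np.where(reads_c, ord("C"), ord("T"))
    nc_idx = np.array(spec.noncpg_c_indices, dtype=int)
    if nc_idx.size:
        stays_c = rng.random((n, nc_idx.size)) < noise.incomplete_conversion
        mol[:, nc_idx] = np.where(stays_c, ord("C"), ord("T"))

    if noise.seq_error > 0:
        err = rng.random((n, L)) < noise.seq_error
        if err.any():
            cur = _BASE_INDEX[mol[err]]
            mol[err] = _BASES[(cur + 1 + rng.integers(0, 3, cur.shape)) % 4]

    qual = _QUAL_CHARS[rng.choice(3, size=(n, L), p=_QUAL_PROBS)]
    rl = min(read_len, L)
    pairs = []
    for i in range(n):
        s = mol[i].tobytes().decode("ascii")
        q = qual[i].tobytes().decode("ascii")
        r1 = FastqRead(f"{id_prefix}:{i}/1", s[:rl], q[:rl])
        r2 = FastqRead(f"{id_prefix}:{i}/2", revcomp(s[-rl:]), q[-rl:][::-1])
        pairs.append((r1, r2))
    return pairs


def emit_control_reads(control_spec: AmpliconSpec, n: int, noise: NoiseModel,
                       rng: np.random.Generator, read_len: int = 251,
                       ) -> list[tuple[FastqRead, FastqRead]]:
    """Fully unmethylated spike-in control read pairs (M13mp18-style role)."""
    patterns = np.zeros((n, control_spec.n_cpg), dtype=np.int8)
    return emit_reads(patterns, control_spec, noise, "BS", rng,
                      read_len=read_len, id_prefix="control")


# ---------------------------------------------------------------------------
# cohort design

@dataclass(frozen=True)
class BehaviorCoupling:
    """Scores as alpha + beta * f_class + Gaussian noise (arbitrary units).

    DV falls and OA/CP rise under treatment in the emulated design, so DV
    and OA couple positively and CP negatively to the treatment-responsive
    class frequency.
    """

    class_index: int = 6
    dv: tuple = (10.0, 40.0, 1.0)     # (alpha, beta, noise sd)
    oa: tuple = (5.0, 30.0, 0.8)
    cp: tuple = (8.0, -35.0, 0.9)


@dataclass
class CohortConfig:
    n_per_group: int = 5
    reads_per_sample: int = 5000
    read_len: int = 251
    control_reads: int = 2000
    flip_rate: float = 0.03
    epitypes_per_class: int = 3
    noise: NoiseModel = field(default_factory=NoiseModel)
    coupling: BehaviorCoupling = field(default_factory=BehaviorCoupling)
    tph1a_n_cpg: int = 11
    tph1a_length: int = 318
    bdnf_n_cpg: int = 21
    bdnf_length: int = 417
    # group-level average methylation (%) and its standard error over
    # n_per_group fish, per (tissue, group), for the Tph1A-like amplicon
    tph1a_mean_pct: dict = field(default_factory=lambda: {
        ("brain", "CTRL"): 51.24, ("brain", "PROBIO"): 53.2,
        ("gut", "CTRL"): 70.38, ("gut", "PROBIO"): 62.1,
    })
    tph1a_se_pct: dict = field(default_factory=lambda: {
        ("brain", "CTRL"): 0.8, ("brain", "PROBIO"): 2.1,
        ("gut", "CTRL"): 4.0, ("gut", "PROBIO"): 1.4,
    })
    # high-weight mixture component (brain PROBIO) and the concentrated
    # treatment-responsive class component (gut PROBIO)
    brain_probio_high_weight: float = 0.2
    brain_probio_high_p: float = 0.95
    gut_probio_class6_weight: float = 0.35
    bdnf_mean_pct: dict = field(default_factory=lambda: {
        "brain": 0.41, "gut": 0.72})
    bdnf_se_pct: dict = field(default_factory=lambda: {
        "brain": 0.034, "gut": 0.06})


def _binom_weights(n: int, p: float) -> np.ndarray:
    return sps.binom.pmf(np.arange(n + 1), n, p)


def group_class_weights(cfg: CohortConfig, tissue: str, group: str) -> np.ndarray:
    """Pre-flip class-weight vector whose post-flip mean hits the target.

    The printed group means are what the pipeline observes, so the target
    is inverted through the conversion-noise floor (incomplete/over-
    conversion) and then through site-flip noise epsilon, which moves the
    class mean toward N/2 (mu' = mu(1-2e) + eN), before constructing the
    binomial / mixture shapes: unimodal for CTRL tissues, a high-class
    component added for brain PROBIO (reshuffling at nearly fixed mean), a
    concentrated responsive-class component for gut PROBIO.
    """
    n = cfg.tph1a_n_cpg
    e = cfg.flip_rate
    m_obs = cfg.tph1a_mean_pct[(tissue, group)] / 100.0
    inc, over = cfg.noise.incomplete_conversion, cfg.noise.over_conversion
    m_true = (m_obs - inc) / (1.0 - over - inc)
    mu_target = m_true * n
    mu_star = (mu_target - e * n) / (1.0 - 2.0 * e)
    if group == "CTRL":
        return _binom_weights(n, mu_star / n)
    if tissue == "brain":
        lam = cfg.brain_probio_high_weight
        hi = _binom_weights(n, cfg.brain_probio_high_p)
        p_low = (mu_star - lam * n * cfg.brain_probio_high_p) / ((1 - lam) * n)
        return (1 - lam) * _binom_weights(n, p_low) + lam * hi
    lam = cfg.gut_probio_class6_weight
    k6 = cfg.coupling.class_index
    delta = np.zeros(n + 1)
    delta[k6] = 1.0
    p_rest = (mu_star - lam * k6) / ((1 - lam) * n)
    return (1 - lam) * _binom_weights(n, p_rest) + lam * delta


def _epitypes_for_weights(class_weights: np.ndarray, n_cpg: int,
                          per_class: int, flip_rate: float,
                          rng: np.random.Generator) -> MixtureModel:
    """Materialize class weights as concrete epitype patterns.

    Each class with non-negligible weight is represented by up to
    ``per_class`` random patterns of that Hamming weight, splitting the
    class weight equally — distinct subpopulations that share a
    methylation load but not its positions.
    """
    epitypes, weights = [], []
    for k, w in enumerate(class_weights):
        if w < 1e-9:
            continue
        n_types = 1 if k in (0, n_cpg) else per_class
        for _ in range(n_types):
            pat = np.zeros(n_cpg, dtype=np.int8)
            pat[rng.choice(n_cpg, size=k, replace=False)] = 1
            epitypes.append(pat)
            weights.append(w / n_types)
    weights = np.array(weights)
    return MixtureModel(np.array(epitypes), weights / weights.sum(), flip_rate)


def _dirichlet_concentration(model: MixtureModel, target_sd_classes: float
                             ) -> float:
    """Concentration making the between-fish SD of the true mean match.

    Under Dirichlet(c*w) jitter of epitype weights, the variance of the
    fish-level mean class is Var_w(mu_e)/(c+1), with mu_e the post-flip
    mean class of epitype e.
    """
    e = model.flip_rate
    mu_e = model.epitypes.sum(axis=1) * (1 - 2 * e) + e * model.n_cpg
    var_w = float(np.sum(model.weights * mu_e ** 2)
                  - np.sum(model.weights * mu_e) ** 2)
    if target_sd_classes <= 0:
        return 1e6
    return max(2.0, var_w / target_sd_classes ** 2 - 1.0)


def jitter_mixture(model: MixtureModel, concentration: float,
                   rng: np.random.Generator) -> MixtureModel:
    """Per-fish epitype weights drawn from Dirichlet around the group's."""
    alpha = np.maximum(model.weights * concentration, 1e-6)
    w = rng.dirichlet(alpha)
    return MixtureModel(model.epitypes, w, model.flip_rate)


@dataclass
class SampleSim:
    sample_id: str
    fish: str
    tissue: str
    group: str
    chemistry: str
    amplicon: str
    pairs: list
    scores: dict
    truth: dict


@dataclass
class CohortSim:
    config: CohortConfig
    seed: int
    amplicons: dict          # name -> AmpliconSpec
    samples: list            # SampleSim
    control_pairs: list

    def sample_sheet_rows(self) -> list[dict]:
        rows = []
        for s in self.samples:
            rows.append({
                "sample_id": s.sample_id, "fish": s.fish,
                "fastq1": f"{s.sample_id}_R1.fastq.gz",
                "fastq2": f"{s.sample_id}_R2.fastq.gz",
                "tissue": s.tissue, "group": s.group,
                "chemistry": s.chemistry, "amplicon": s.amplicon,
                **s.scores,
            })
        return rows


def _behavior_scores(f_class: float, coupling: BehaviorCoupling,
                     rng: np.random.Generator) -> dict:
    out = {}
    for name, (alpha, beta, sd) in (("DV", coupling.dv), ("OA", coupling.oa),
                                    ("CP", coupling.cp)):
        out[name] = float(alpha + beta * f_class + rng.normal(0.0, sd))
    return out


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0
                    ) -> CohortSim:
    """Simulate the full two-tissue, two-group, two-chemistry cohort.

    Per fish and tissue: one jittered epiallele model shared by the BS and
    oxBS libraries of the Tph1A-like amplicon (independent molecules), one
    independent-site model for the BDNF-like amplicon (BS only), and one
    set of behavior scores coupled to the fish's true responsive-class
    frequency. Ground truth (exact expected per-CpG p, class frequencies
    and the realized drawn class counts) is recorded per sample.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    tph1a = make_amplicon(cfg.tph1a_n_cpg, cfg.tph1a_length,
                          rng.integers(2**31), name="Tph1A_like")
    bdnf = make_amplicon(cfg.bdnf_n_cpg, cfg.bdnf_length,
                         rng.integers(2**31), name="BDNF_like")
    control = make_amplicon(6, 220, rng.integers(2**31), name="unmeth_control")
    samples = []
    k_resp = cfg.coupling.class_index
    for tissue in ("brain", "gut"):
        for group in ("CTRL", "PROBIO"):
            weights = group_class_weights(cfg, tissue, group)
            base = _epitypes_for_weights(weights, cfg.tph1a_n_cpg,
                                         cfg.epitypes_per_class,
                                         cfg.flip_rate, rng)
            sd_cls = (cfg.tph1a_se_pct[(tissue, group)]
                      * np.sqrt(cfg.n_per_group) / 100.0 * cfg.tph1a_n_cpg)
            conc = _dirichlet_concentration(base, sd_cls)
            # BDNF-like: site profile with two high-methylation upstream
            # sites, scaled to the tissue's tiny mean
            u = np.ones(cfg.bdnf_n_cpg)
            u[:2] = 4.0
            inc = cfg.noise.incomplete_conversion
            over = cfg.noise.over_conversion
            m_b = (cfg.bdnf_mean_pct[tissue] / 100.0 - inc) / (1 - over - inc)
            p_bdnf = np.clip(m_b * cfg.bdnf_n_cpg * u / u.sum(), 0.0, 1.0)
            cv = (cfg.bdnf_se_pct[tissue] * np.sqrt(cfg.n_per_group)
                  / cfg.bdnf_mean_pct[tissue])
            kappa = 1.0 / cv ** 2
            for i in range(1, cfg.n_per_group + 1):
                fish = f"{tissue}_{group}_{i}"
                model = jitter_mixture(base, conc, rng)
                f_resp = float(expected_class_freqs(model)[k_resp])
                scores = _behavior_scores(f_resp, cfg.coupling, rng)
                for chem in ("BS", "oxBS"):
                    pats = sample_epialleles(model, cfg.reads_per_sample, rng)
                    sid = f"{fish}_{chem}_Tph1A"
                    pairs = emit_reads(pats, tph1a, cfg.noise, chem, rng,
                                       cfg.read_len, id_prefix=sid)
                    hm = cfg.noise.hmc_fraction if chem == "oxBS" else 0.0
                    obs_p = expected_per_cpg_p(model, hm, cfg.noise)
                    truth = {
                        "class_freqs": expected_class_freqs(model, hm).tolist(),
                        "per_cpg_p": expected_per_cpg_p(model, hm).tolist(),
                        "mean_pct": float(expected_per_cpg_p(model, hm).mean()
                                          * 100.0),
                        "observed_class_freqs": expected_class_freqs(
                            model, hm, cfg.noise).tolist(),
                        "observed_per_cpg_p": obs_p.tolist(),
                        "observed_mean_pct": float(obs_p.mean() * 100.0),
                        "realized_class_counts": np.bincount(
                            pats.sum(axis=1),
                            minlength=cfg.tph1a_n_cpg + 1).tolist(),
                        "f_responsive": f_resp,
                    }
                    samples.append(SampleSim(sid, fish, tissue, group, chem,
                                             "Tph1A_like", pairs, scores, truth))
                p_fish = np.clip(p_bdnf * rng.gamma(kappa, 1.0 / kappa), 0, 1)
                bmodel = IndependentModel(p_fish)
                pats = sample_epialleles(bmodel, cfg.reads_per_sample, rng)
                sid = f"{fish}_BS_BDNF"
                pairs = emit_reads(pats, bdnf, cfg.noise, "BS", rng,
                                   cfg.read_len, id_prefix=sid)
                obs_p = expected_per_cpg_p(bmodel, 0.0, cfg.noise)
                truth = {
                    "class_freqs": expected_class_freqs(bmodel).tolist(),
                    "per_cpg_p": expected_per_cpg_p(bmodel).tolist(),
                    "mean_pct": float(p_fish.mean() * 100.0),
                    "observed_class_freqs": expected_class_freqs(
                        bmodel, 0.0, cfg.noise).tolist(),
                    "observed_per_cpg_p": obs_p.tolist(),
                    "observed_mean_pct": float(obs_p.mean() * 100.0),
                    "realized_class_counts": np.bincount(
                        pats.sum(axis=1), minlength=cfg.bdnf_n_cpg + 1).tolist(),
                    "f_responsive": None,
                }
                samples.append(SampleSim(sid, fish, tissue, group, "BS",
                                         "BDNF_like", pairs, scores, truth))
    control_pairs = emit_control_reads(control, cfg.control_reads, cfg.noise,
                                       rng, cfg.read_len)
    return CohortSim(cfg, seed, {"Tph1A_like": tph1a, "BDNF_like": bdnf,
                                 "unmeth_control": control},
                     samples, control_pairs)


# ---------------------------------------------------------------------------
# file output

def _open_text_for_write(path):
    # mtime=0 keeps gzip output byte-identical across reruns
    if str(path).endswith(".gz"):
        import io
        return io.TextIOWrapper(gzip.GzipFile(str(path), "wb", mtime=0))
    return open(str(path), "wt")


def write_fastq_pair(pairs, path1, path2) -> None:
    for path, mate in ((path1, 0), (path2, 1)):
        with _open_text_for_write(path) as fh:
            for pair in pairs:
                r = pair[mate]
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.qualities}\n")


def write_cohort(sim: CohortSim, outdir) -> None:
    """Write FASTQ pairs, sample sheet TSV, references and truth JSON."""
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in sim.samples:
        write_fastq_pair(s.pairs, outdir / f"{s.sample_id}_R1.fastq.gz",
                         outdir / f"{s.sample_id}_R2.fastq.gz")
    write_fastq_pair(sim.control_pairs, outdir / "control_R1.fastq.gz",
                     outdir / "control_R2.fastq.gz")
    pd.DataFrame(sim.sample_sheet_rows()).to_csv(
        outdir / "sample_sheet.tsv", sep="\t", index=False)
    with open(outdir / "references.fasta", "w") as fh:
        for name, spec in sim.amplicons.items():
            fh.write(f">{name}\n{spec.sequence}\n")
    truth = {
        "seed": sim.seed,
        "amplicons": {n: {"tss_index": s.tss_index,
                          "cpg_coords": list(s.cpg_coords)}
                      for n, s in sim.amplicons.items()},
        "samples": {s.sample_id: {"tissue": s.tissue, "group": s.group,
                                  "chemistry": s.chemistry,
                                  "amplicon": s.amplicon,
                                  "scores": s.scores, **s.truth}
                    for s in sim.samples},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
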