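"""Seeded generators for synthetic direct-RNA modification data.

Three generators cover the statistical structure the analysis pipeline
assumes:

* per-base feature tables for a paired design (a treated sample carrying a
  modification substoichiometrically, and a control carrying at most a
  residual level), with two-population feature distributions per k-mer;
* per-read modification-probability (modProb) streams whose class medians
  are calibrated to ~0.0 for unmodified and ~0.7 for modified adenosines;
* multi-site transcripts in which pairs of sites carry a tunable per-read
  co-occurrence, with exact marginal stoichiometries.

Ground truth (per-read labels, per-site stoichiometry, per-pair coupling)
is retained for every generated read so that recovery can be tested.

Distribution families: signal intensity is Normal with a per-k-mer baseline
and an additive shift of ``si_shift_sd`` standard deviations on modified
reads; trace and modProb values are Beta pairs (high trace / near-zero
modProb when unmodified, near-zero trace / high modProb when modified);
dwell times are LogNormal with a multiplicative factor on modified reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .errors import ConfigError
from .feature_io import CALL_COLUMNS, FEATURES_RNA002, decode_modprob, encode_modprob

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """Per-feature effect of the modification on the measured features.

    si_shift_sd
        Additive shift of the signal-intensity mean on modified reads, in
        units of the per-k-mer standard deviation.
    trace_unmod / trace_mod
        Beta(a, b) parameters of the reference-base trace for unmodified
        (high, near 1) and modified (near 0) reads.
    mp_unmod / mp_mod
        Beta parameters of the basecaller modification/error probability.
    dwell_factor
        Multiplicative factor applied to the central dwell time of modified
        reads (1.0 = no dwell effect).
    """

    si_shift_sd: float = 2.0
    trace_unmod: tuple[float, float] = (10.0, 1.5)
    trace_mod: tuple[float, float] = (1.5, 10.0)
    mp_unmod: tuple[float, float] = (1.0, 15.0)
    mp_mod: tuple[float, float] = (6.0, 3.0)
    dwell_factor: float = 1.5


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic feature/modProb generators.

    stoichiometry ``s`` is the per-site modified fraction in the treated
    sample; ``residual`` is the leftover modification rate of the control
    (knockout samples are rarely completely devoid of the mark; 0.03 is a
    realistic default for a KO-like control, 0 models an IVT control).
    """

    seed: int = 0
    n_reads_per_sample: int = 100
    n_affected_kmers: int = 5
    n_unaffected_kmers: int = 5
    positions_per_kmer: int = 1
    stoichiometry: float = 0.5
    residual: float = 0.03
    effect: EffectSpec = field(default_factory=EffectSpec)
    modprob_medians: tuple[float, float] = (0.0, 0.7)
    n_sites: int = 10
    n_reads: int = 1000
    read_prefix: str = "read"

    def __post_init__(self) -> None:
        if not 0.0 <= self.residual <= self.stoichiometry <= 1.0:
            raise ConfigError(
                f"need 0 <= residual <= stoichiometry <= 1, got "
                f"residual={self.residual}, stoichiometry={self.stoichiometry}"
            )


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests.

    read_labels: one row per (read_id, ref_id, pos, sample) with the true
    modification status.  site_stoichiometry: one row per site with the
    target modified fraction.  pair_coupling: one row per site pair with the
    correlation used (co-occurrence generator only).
    """

    read_labels: pd.DataFrame
    site_stoichiometry: pd.DataFrame
    pair_coupling: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# modProb Beta calibration
# ---------------------------------------------------------------------------

def modprob_beta_params(median_unmod: float, median_mod: float,
                        concentration: float = 9.0):
    """Beta parameters hitting the requested class medians.

    The modified class uses Beta(c*p, c*(1-p)) at fixed concentration ``c``
    and solves for ``p``; the unmodified class uses a sharp Beta(0.3, b).
    A target median the family cannot reach raises :class:`ConfigError`.
    """
    if not 0.0 <= median_unmod < median_mod <= 1.0:
        raise ConfigError("need 0 <= median_unmod < median_mod <= 1")

    def med_mod(p):
        return stats.beta.median(concentration * p, concentration * (1 - p)) - median_mod

    try:
        p = brentq(med_mod, 1e-4, 1 - 1e-4)
    except ValueError as exc:  # pragma: no cover - family spans (0,1)
        raise ConfigError(f"modified median {median_mod} unreachable") from exc
    mod_ab = (concentration * p, concentration * (1 - p))

    a_u = 0.3
    if median_unmod < 0.005:
        unmod_ab = (a_u, 40.0)
    else:
        def med_unmod(b):
            return stats.beta.median(a_u, b) - median_unmod
        lo, hi = 0.31, 5000.0
        if med_unmod(lo) < 0 or med_unmod(hi) > 0:
            raise ConfigError(f"unmodified median {median_unmod} unreachable")
        unmod_ab = (a_u, brentq(med_unmod, lo, hi))
    realized = stats.beta.median(*unmod_ab)
    if realized > max(median_unmod + 0.01, 0.01):
        raise ConfigError(
            f"unmodified median target {median_unmod} unreachable "
            f"(realized {realized:.4f})"
        )
    return unmod_ab, mod_ab


def _draw_modprob(rng: np.random.Generator, modified: np.ndarray,
                  unmod_ab, mod_ab) -> np.ndarray:
    """Draw modProbs per base, quantized through the 256-bin byte encoding."""
    p = np.where(
        modified,
        rng.beta(*mod_ab, size=modified.shape),
        rng.beta(*unmod_ab, size=modified.shape),
    )
    return decode_modprob(encode_modprob(p))


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def _random_kmers(rng: np.random.Generator, n: int, exclude=()) -> list[str]:
    """Distinct random A-centered 7-mers."""
    out: list[str] = []
    seen = set(exclude)
    while len(out) < n:
        flanks = rng.integers(0, 4, size=6)
        kmer = "".join(_BASES[flanks[:3]]) + "A" + "".join(_BASES[flanks[3:]])
        if kmer not in seen:
            seen.add(kmer)
            out.append(kmer)
    return out


def build_reference(kmers: list[str], positions_per_kmer: int = 1,
                    spacer: str = "CCCCC") -> tuple[str, pd.DataFrame]:
    """Concatenate 7-mers into one reference with C-spacers.

    Returns the sequence and a table (kmer, pos) of the central-base
    coordinate of every placed 7-mer occurrence.
    """
    seq_parts = [spacer]
    rows = []
    offset = len(spacer)
    for kmer in kmers:
        for _ in range(positions_per_kmer):
            rows.append((kmer, offset + 3))
            seq_parts.append(kmer + spacer)
            offset += 7 + len(spacer)
    return "".join(seq_parts), pd.DataFrame(rows, columns=["kmer", "pos"])


# ---------------------------------------------------------------------------
# feature-table generator
# ---------------------------------------------------------------------------

def simulate_feature_dataset(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate paired control/treated per-base feature tables.

    The treated sample is modified at rate ``stoichiometry`` at sites whose
    centered 7-mer belongs to the affected set; the control at rate
    ``residual``.  Unaffected k-mers are distributionally identical across
    samples.  Modified reads draw every feature from the shifted family of
    ``config.effect``.
    """
    rng = np.random.default_rng(config.seed)
    eff = config.effect
    affected = _random_kmers(rng, config.n_affected_kmers)
    unaffected = _random_kmers(rng, config.n_unaffected_kmers, exclude=affected)
    seq, sites = build_reference(affected + unaffected, config.positions_per_kmer)
    sites["affected"] = sites["kmer"].isin(affected)

    # per-k-mer signal baseline
    kmer_mu = {k: rng.normal(80.0, 5.0) for k in affected + unaffected}
    kmer_sd = 4.0

    frames, truth_rows = [], []
    for site in sites.itertuples(index=False):
        for sample, rate in (("control", config.residual), ("treated", config.stoichiometry)):
            n = config.n_reads_per_sample
            modified = rng.random(n) < (rate if site.affected else 0.0)
            si = rng.normal(kmer_mu[site.kmer], kmer_sd, n)
            si[modified] += eff.si_shift_sd * kmer_sd
            mp = np.where(modified, rng.beta(*eff.mp_mod, n), rng.beta(*eff.mp_unmod, n))
            tr = np.where(modified, rng.beta(*eff.trace_mod, n), rng.beta(*eff.trace_unmod, n))
            dt = rng.lognormal(np.log(10.0), 0.3, n)
            dt[modified] *= eff.dwell_factor
            dt10 = rng.lognormal(np.log(10.0), 0.3, n)
            # split the remaining trace mass over the three non-reference bases
            rest = (1.0 - tr)[:, None] * rng.dirichlet(np.ones(3), n)
            traces = {"TA": tr, "TC": rest[:, 0], "TG": rest[:, 1], "TT": rest[:, 2]}
            read_ids = [f"{sample}_{site.pos}_{i:05d}" for i in range(n)]
            frames.append(pd.DataFrame({
                "read_id": read_ids,
                "ref_id": "synthetic_ref",
                "pos": site.pos,
                "strand": "+",
                "ref_base": "A",
                "kmer": site.kmer,
                "sample": sample,
                "SI": si, "MP": mp, "DT": dt, "DT10": dt10,
                "TR": traces["TA"], "TA": traces["TA"],
                "TC": traces["TC"], "TG": traces["TG"], "TT": traces["TT"],
            }))
            truth_rows.append(pd.DataFrame({
                "read_id": read_ids, "ref_id": "synthetic_ref",
                "pos": site.pos, "sample": sample, "modified": modified,
            }))

    features = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        read_labels=pd.concat(truth_rows, ignore_index=True),
        site_stoichiometry=pd.DataFrame({
            "ref_id": "synthetic_ref",
            "pos": sites["pos"],
            "kmer": sites["kmer"],
            "affected": sites["affected"],
            "stoichiometry": np.where(sites["affected"], config.stoichiometry, 0.0),
        }),
    )
    features.attrs["reference"] = seq
    return features, truth


# ---------------------------------------------------------------------------
# modProb read generator
# ---------------------------------------------------------------------------

def simulate_modprob_dataset(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate full-length reads with per-adenosine modProbs.

    ``config.n_reads`` reads each cover ``config.n_sites`` adenosine sites
    of one synthetic transcript; every read is independently modified at
    each site with probability ``stoichiometry``, so the realized per-site
    modified fraction is a Binomial(n_reads, s) draw.
    """
    rng = np.random.default_rng(config.seed)
    unmod_ab, mod_ab = modprob_beta_params(*config.modprob_medians)
    n_reads, n_sites = config.n_reads, config.n_sites
    positions = 10 + 20 * np.arange(n_sites)
    modified = rng.random((n_reads, n_sites)) < config.stoichiometry
    probs = _draw_modprob(rng, modified, unmod_ab, mod_ab)

    read_ids = np.array([f"{config.read_prefix}_{i:06d}" for i in range(n_reads)])
    calls = pd.DataFrame({
        "read_id": np.repeat(read_ids, n_sites),
        "ref_id": "synthetic_tx",
        "pos": np.tile(positions, n_reads),
        "strand": "+",
        "base": "A",
        "mod_prob": probs.ravel(),
    })[CALL_COLUMNS]
    truth = GroundTruth(
        read_labels=pd.DataFrame({
            "read_id": np.repeat(read_ids, n_sites),
            "ref_id": "synthetic_tx",
            "pos": np.tile(positions, n_reads),
            "modified": modified.ravel(),
        }),
        site_stoichiometry=pd.DataFrame({
            "ref_id": "synthetic_tx", "pos": positions,
            "stoichiometry": config.stoichiometry,
        }),
    )
    return calls, truth


# ---------------------------------------------------------------------------
# co-occurring site pairs
# ---------------------------------------------------------------------------

def _joint_bernoulli_p11(fa: float, fb: float, rho: float) -> float:
    """Joint success probability of two correlated Bernoullis.

    ``rho`` is the Pearson correlation of the two indicators; the implied
    P(both modified) must respect the Fréchet bounds.
    """
    p11 = fa * fb + rho * np.sqrt(fa * (1 - fa) * fb * (1 - fb))
    lo, hi = max(0.0, fa + fb - 1.0), min(fa, fb)
    if not lo - 1e-12 <= p11 <= hi + 1e-12:
        raise ConfigError(
            f"rho={rho} not attainable for marginals ({fa}, {fb}): "
            f"implied P(1,1)={p11:.4f} outside Fréchet bounds [{lo:.4f}, {hi:.4f}]"
        )
    return float(np.clip(p11, lo, hi))


def simulate_cooccurring_transcripts(
    n_transcripts: int,
    coverage: int,
    fa: float,
    fb: float,
    rho: float,
    seed: int = 0,
    modprob_medians: tuple[float, float] = (0.0, 0.7),
    min_site_distance: int = 20,
    max_site_distance: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate transcripts with one pair of coupled sites each.

    Every transcript has ``coverage`` full-length reads spanning both
    sites.  Per read, the pair of modification indicators is drawn from the
    joint Bernoulli with marginals (fa, fb) and correlation ``rho``:
    ``rho = 0`` makes co-modification the product of the marginals, positive
    ``rho`` shifts mass toward co-modification while preserving both
    marginals.  Site distances are log-uniform across transcripts.

    Returns (calls, isoform_assignments, truth).
    """
    if not (0 < fa < 1 and 0 < fb < 1):
        raise ConfigError("marginal frequencies must lie strictly in (0, 1)")
    p11 = _joint_bernoulli_p11(fa, fb, rho)
    p10, p01 = fa - p11, fb - p11
    p00 = 1.0 - p11 - p10 - p01

    rng = np.random.default_rng(seed)
    unmod_ab, mod_ab = modprob_beta_params(*modprob_medians)
    distances = np.exp(rng.uniform(
        np.log(min_site_distance), np.log(max_site_distance), n_transcripts
    )).astype(int)

    call_frames, assign_rows, truth_rows, label_frames = [], [], [], []
    for t in range(n_transcripts):
        tid = f"tx_{t:04d}"
        pos_a, pos_b = 50, 50 + distances[t]
        joint = rng.choice(4, size=coverage, p=[p11, p10, p01, p00])
        mod_a, mod_b = joint <= 1, (joint == 0) | (joint == 2)
        modified = np.column_stack([mod_a, mod_b])
        probs = _draw_modprob(rng, modified, unmod_ab, mod_ab)
        read_ids = np.array([f"{tid}_read_{i:05d}" for i in range(coverage)])
        call_frames.append(pd.DataFrame({
            "read_id": np.repeat(read_ids, 2),
            "ref_id": tid,
            "pos": np.tile([pos_a, pos_b], coverage),
            "strand": "+",
            "base": "A",
            "mod_prob": probs.ravel(),
        }))
        label_frames.append(pd.DataFrame({
            "read_id": np.repeat(read_ids, 2),
            "ref_id": tid,
            "pos": np.tile([pos_a, pos_b], coverage),
            "modified": modified.ravel(),
        }))
        assign_rows.append(pd.DataFrame({
            "read_id": read_ids, "transcript_id": tid, "class": "unique",
        }))
        truth_rows.append((tid, pos_a, pos_b, fa, fb, rho, p11))

    calls = pd.concat(call_frames, ignore_index=True)[CALL_COLUMNS]
    assignments = pd.concat(assign_rows, ignore_index=True)
    pair_truth = pd.DataFrame(
        truth_rows,
        columns=["transcript_id", "pos_a", "pos_b", "fa", "fb", "rho", "p11"],
    )
    truth = GroundTruth(
        read_labels=pd.concat(label_frames, ignore_index=True),
        site_stoichiometry=pd.DataFrame({
            "ref_id": np.repeat(pair_truth["transcript_id"], 2),
            "pos": pair_truth[["pos_a", "pos_b"]].to_numpy().ravel(),
            "stoichiometry": np.tile([fa, fb], n_transcripts),
        }),
        pair_coupling=pair_truth,
    )
    return calls, assignments, truth


# ---------------------------------------------------------------------------
# in-silico mixtures
# ---------------------------------------------------------------------------

def mix_pools(modified_pool: pd.DataFrame, unmodified_pool: pd.DataFrame,
              target_stoichiometry: float, n: int, seed: int = 0
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw an in-silico mixture of reads at a target modified fraction.

    Exactly ``round(n * target)`` read IDs are drawn without replacement
    from the modified pool and the remainder from the unmodified pool.
    Returns (mixed calls, log of sampled read IDs with their source pool).
    """
    if not 0.0 <= target_stoichiometry <= 1.0:
        raise ConfigError("target stoichiometry must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mod_ids = modified_pool["read_id"].unique()
    unmod_ids = unmodified_pool["read_id"].unique()
    n_mod = int(round(n * target_stoichiometry))
    n_unmod = n - n_mod
    if n_mod > len(mod_ids):
        raise ConfigError(
            f"modified pool too small: need {n_mod} reads, have {len(mod_ids)} "
            f"(deficit {n_mod - len(mod_ids)})"
        )
    if n_unmod > len(unmod_ids):
        raise ConfigError(
            f"unmodified pool too small: need {n_unmod} reads, have "
            f"{len(unmod_ids)} (deficit {n_unmod - len(unmod_ids)})"
        )
    take_mod = rng.choice(mod_ids, size=n_mod, replace=False)
    take_unmod = rng.choice(unmod_ids, size=n_unmod, replace=False)
    mixed = pd.concat([
        modified_pool[modified_pool["read_id"].isin(take_mod)],
        unmodified_pool[unmodified_pool["read_id"].isin(take_unmod)],
    ], ignore_index=True)
    log = pd.DataFrame({
        "read_id": np.concatenate([take_mod, take_unmod]),
        "source": ["modified"] * n_mod + ["unmodified"] * n_unmod,
    })
    return mixed, log
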