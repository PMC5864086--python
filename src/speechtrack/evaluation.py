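"""Calibration and ground-truth-recovery experiments.

Self-contained experiments that exercise the pipeline end to end on
synthetic data and report scalar summaries: estimator accuracy against
the closed-form Gaussian MI, null calibration of the estimator and of
the cluster permutation test, recovery of the injected stimulus-brain
lag, monotonicity of MI in tracking SNR, spatial recovery of the
injected effect region, and detection of injected phase-amplitude
coupling with its frequency controls.  Problem sizes are chosen so the
whole battery runs in minutes on one core; each function documents the
sizes it uses.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _st

from .cluster_stats import (
    cluster_permutation,
    critical_t,
    fdr_adjust,
    lattice_adjacency,
    t_from_diffs,
)
from .infotheory import copula_normalise, gaussian_mi
from .pac import pac_condition_contrast
from .speech_features import CANONICAL_BANDS
from .synthetic_data import SynthConfig, generate_corpus, generate_participant
from .tracking import condition_contrast, lag_grid, prepare_trials, tracking_mi

__all__ = [
    "mi_estimator_max_error",
    "independence_calibration",
    "cluster_false_positive_rate",
    "recovered_lag_ms",
    "snr_monotonicity",
    "effect_region_recovery",
    "pac_detection",
]


def _sub(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *tags]))


def mi_estimator_max_error(
    seed: int = 0, rhos: tuple = (0.0, 0.3, 0.6, 0.9), n: int = 10_000
) -> float:
    """Max |error| (bits) of copula MI vs -1/2 log2(1 - rho^2) for Gaussians."""
    rng = _sub(seed, 1)
    worst = 0.0
    for rho in rhos:
        cov = [[1.0, rho], [rho, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        est = gaussian_mi(
            copula_normalise(xy[:, 0]), copula_normalise(xy[:, 1]), bias_correct=True
        ).bits
        truth = -0.5 * np.log2(1.0 - rho**2)
        worst = max(worst, abs(est - truth))
    return worst


def independence_calibration(seed: int = 0, n_runs: int = 200, n: int = 500) -> dict:
    """Bias-corrected MI under independence: mean and SE over repeated runs."""
    rng = _sub(seed, 2)
    vals = []
    for _ in range(n_runs):
        x = copula_normalise(rng.standard_normal(n))
        y = copula_normalise(rng.standard_normal(n))
        vals.append(gaussian_mi(x, y, bias_correct=True, clamp=False).bits)
    vals = np.asarray(vals)
    return {
        "mean_bits": float(vals.mean()),
        "se_bits": float(vals.std(ddof=1) / np.sqrt(n_runs)),
        "n_runs": n_runs,
    }


def cluster_false_positive_rate(
    seed: int = 0,
    n_rounds: int = 200,
    n_perm: int = 500,
    grid_shape: tuple = (6, 6, 6),
    n_participants: int = 20,
) -> float:
    """Fraction of pure-noise experiments yielding any p <= .05 cluster.

    Each round draws independent normal difference maps for every
    virtual participant on a regular lattice and runs the full
    dependent-t + sign-flip cluster permutation path.
    """
    rng = _sub(seed, 3)
    shape = tuple(grid_shape)
    coords = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3).astype(float)
    adjacency = lattice_adjacency(coords)
    n_points = coords.shape[0]
    t_crit = critical_t(n_participants)
    hits = 0
    for _ in range(n_rounds):
        diffs = rng.standard_normal((n_participants, n_points))
        clusters = cluster_permutation(
            t_from_diffs(diffs), diffs, adjacency, n_perm=n_perm, t_crit=t_crit,
            seed=rng,
        )
        if any(c.p_cluster <= 0.05 for c in clusters):
            hits += 1
    return hits / n_rounds


def _small_tracking_cfg(seed: int, snr: float, n_trials: int = 15) -> SynthConfig:
    return SynthConfig(
        n_sentences=20,
        n_trials=n_trials,
        n_participants=1,
        grid_shape=(2, 2, 2),
        effect_region=np.array([1]),
        tracking_snr_correct=snr,
        tracking_snr_incorrect=snr,
        pac_depth_correct=0.0,
        pac_depth_incorrect=0.0,
        master_seed=seed,
    )


def recovered_lag_ms(seed: int = 0, true_lag_ms: float = 100.0) -> float:
    """Lag maximising single-lag MI when tracking is injected at a known lag.

    Uses the wideband phoneme band, where the analytic-signal envelope
    decorrelates fast enough to resolve 20-ms lag steps.
    """
    cfg = _small_tracking_cfg(seed, snr=0.8)
    cfg.neural_lag_ms = true_lag_ms
    _, envelopes = generate_corpus(cfg)
    raw = generate_participant(cfg, envelopes, 0)
    trials = prepare_trials(raw, CANONICAL_BANDS["phoneme"])
    curve = {lag: tracking_mi(trials, 1, [lag]).bits for lag in lag_grid()}
    return float(max(curve, key=curve.get))


def snr_monotonicity(seed: int = 0, n_levels: int = 10, n_reps: int = 20) -> dict:
    """Spearman correlation between tracking SNR and mean lag-summed MI.

    Sweeps ``n_levels`` SNR amplitudes from 0 to 0.9 with ``n_reps``
    independently generated single-participant datasets per level
    (phrase band, one effect grid point).
    """
    levels = np.linspace(0.0, 0.9, n_levels)
    means = []
    for i, snr in enumerate(levels):
        vals = []
        for rep in range(n_reps):
            cfg = _small_tracking_cfg(seed, snr=float(snr), n_trials=12)
            _, envelopes = generate_corpus(cfg, seed=int(np.random.SeedSequence([seed, 41, rep]).generate_state(1)[0] % 2**31))
            raw = generate_participant(cfg, envelopes, participant=100 * i + rep)
            trials = prepare_trials(raw, CANONICAL_BANDS["phrase"])
            vals.append(tracking_mi(trials, 1).bits)
        means.append(np.mean(vals))
    rho = _st.spearmanr(levels, means).statistic
    return {"spearman": float(rho), "mean_mi_bits": [float(m) for m in means]}


def effect_region_recovery(
    seed: int = 0,
    n_participants: int = 20,
    n_trials: int = 30,
    contrast_repeats: int = 5,
    n_perm: int = 200,
) -> dict:
    """Jaccard overlap between the recovered cluster and the injected region.

    Tracking advantage only in correct trials (incorrect SNR = 0) on the
    default 8x8x8 grid with a 3x3x3 effect block; the correct/incorrect
    contrast runs in the phrase band, followed by the dependent-t +
    cluster permutation path; the most significant positive cluster is
    compared against ground truth.
    """
    cfg = SynthConfig(
        n_sentences=40,
        n_trials=n_trials,
        n_participants=n_participants,
        tracking_snr_correct=0.6,
        tracking_snr_incorrect=0.0,
        pac_depth_correct=0.0,
        pac_depth_incorrect=0.0,
        master_seed=seed,
    )
    _, envelopes = generate_corpus(cfg)
    band = CANONICAL_BANDS["phrase"]
    diffs = []
    for p in range(n_participants):
        raw = generate_participant(cfg, envelopes, p)
        trials = prepare_trials(raw, band)
        mc, mi = condition_contrast(
            trials, n_repeats=contrast_repeats, seed=_sub(seed, 5, p)
        )
        diffs.append(mc.mi_bits - mi.mi_bits)
    diffs = np.asarray(diffs)
    adjacency = lattice_adjacency(cfg.grid_coords())
    clusters = cluster_permutation(
        t_from_diffs(diffs), diffs, adjacency, n_perm=n_perm, seed=_sub(seed, 6)
    )
    truth = set(cfg.effect_region.tolist())
    pos = [c for c in clusters if c.sign == "pos"]
    if not pos:
        return {"jaccard": 0.0, "p_cluster": 1.0, "n_cluster_points": 0}
    best = pos[0]
    members = set(best.members.tolist())
    return {
        "jaccard": len(members & truth) / len(members | truth),
        "p_cluster": best.p_cluster,
        "n_cluster_points": len(members),
    }


def pac_detection(
    seed: int = 0,
    n_experiments: int = 50,
    n_participants: int = 10,
    n_trials: int = 24,
    n_repeats: int = 3,
) -> dict:
    """Detection rate of injected delta-beta PAC and control-pair behaviour.

    Each simulated experiment injects coupling (depth 0.8 in correct
    trials, 0 in incorrect; no envelope tracking, isolating the
    coupling) at one of two grid points, runs the region contrast for the
    canonical pair and its three controls across participants, applies
    BH-FDR over the four dependent-t tests, and records whether the
    canonical pair is detected and how often controls reject.
    """
    B = CANONICAL_BANDS
    pairs = [("phrase", "beta"), ("phrase", "alpha"), ("phrase", "theta"), ("word", "beta")]
    detected = 0
    control_rejections = 0
    for e in range(n_experiments):
        cfg = SynthConfig(
            n_sentences=20,
            n_trials=n_trials,
            n_participants=n_participants,
            grid_shape=(2, 1, 1),
            effect_region=np.array([1]),
            pac_region=np.array([1]),
            tracking_snr_correct=0.0,
            tracking_snr_incorrect=0.0,
            pac_depth_correct=0.8,
            pac_depth_incorrect=0.0,
            master_seed=int((seed * 997 + e) % 2**31),
        )
        _, envelopes = generate_corpus(cfg)
        diffs = {pair: [] for pair in pairs}
        for p in range(n_participants):
            raw = generate_participant(cfg, envelopes, p)
            for ph, pw in pairs:
                rc, ri = pac_condition_contrast(
                    raw, B[ph], B[pw], region=np.array([1]),
                    n_repeats=n_repeats, seed=_sub(seed, 7, e, p, int(B[pw].f_lo)),
                )
                diffs[(ph, pw)].append(rc.mi_bits - ri.mi_bits)
        pvals = np.array(
            [_st.ttest_1samp(np.asarray(diffs[pair]), 0.0).pvalue for pair in pairs]
        )
        _, reject = fdr_adjust(pvals, 0.05)
        if reject[0] and np.mean(diffs[pairs[0]]) > 0:
            detected += 1
        control_rejections += int(np.sum(reject[1:]))
    return {
        "detection_rate": detected / n_experiments,
        "control_rejection_rate": control_rejections / (3 * n_experiments),
        "n_experiments": n_experiments,
    }
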