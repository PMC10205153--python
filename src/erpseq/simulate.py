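"""Synthetic inputs for the full pipeline.

Generates design layouts (Latin square), cloze response sets calibrated to
the two-level constraint manipulation (mean entropy near 0.68 bits for the
strong profile and 2.44 bits for the weak one), trial-level amplitudes with
the assumed hierarchical structure, raw epochs with injected component
templates and blink/step artifacts, and stop-signal sessions. Every
generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cloze import ClozeResponseSet, build_predictor_table, center_predictor
from .preprocess import EpochSet, ms_to_sample_range
from .stopsignal import StopSignalSession

__all__ = [
    "TruthParams",
    "DesignLayout",
    "CLOZE_PROFILES",
    "build_design",
    "generate_cloze_responses",
    "generate_predictors",
    "generate_trial_amplitudes",
    "generate_epochs",
    "generate_stop_signal_session",
    "simulate_trial_table",
    "DEFAULT_CHANNELS",
]

CONDITIONS = ("a", "b", "c", "d")

DEFAULT_CHANNELS = [
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC1", "FC2", "T7", "C3", "Cz", "C4", "T8",
    "CP1", "CP2", "P7", "P3", "Pz", "P4", "P8", "POz", "O1", "O2",
]


@dataclass
class TruthParams:
    """Generative counterparts of the model parameters.

    Defaults sit at the empirical scale the pipeline is designed for: a
    constraint slope of -0.26 uV/bit and a residual SD of 8 uV;
    random-effect SDs default to plausible fractions of the prior scales.
    """

    alpha: float = 0.5
    beta_constraint: float = -0.26
    beta_predictability: float = 0.0
    sigma_subject: np.ndarray = field(
        default_factory=lambda: np.array([2.0, 0.3, 0.3])
    )  # intercept, constraint slope, predictability slope
    rho: np.ndarray = field(default_factory=lambda: np.eye(3))
    sigma_item: float = 1.5
    sigma_residual: float = 8.0

    def __post_init__(self):
        self.sigma_subject = np.asarray(self.sigma_subject, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if np.any(self.sigma_subject < 0) or self.sigma_item < 0 or self.sigma_residual < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not np.allclose(self.rho, self.rho.T) or not np.allclose(np.diag(self.rho), 1.0):
            raise ValueError("rho must be symmetric with unit diagonal")
        try:
            np.linalg.cholesky(self.rho + 1e-12 * np.eye(len(self.rho)))
        except np.linalg.LinAlgError:
            raise ValueError("rho must be positive definite") from None


@dataclass
class DesignLayout:
    n_subjects: int
    n_items: int
    table: pd.DataFrame  # subject, item, condition, trial_order, post_question


def build_design(
    n_subjects: int, n_items: int, seed: int = 0, post_question_rate: float = 0.5
) -> DesignLayout:
    """Latin-square assignment: each subject sees each item exactly once,
    with equal per-subject condition counts and ~50% post-question trials."""
    if n_items % 4 != 0:
        raise ValueError("n_items must be divisible by 4")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        conditions = [CONDITIONS[(i + s) % 4] for i in range(n_items)]
        order = rng.permutation(n_items)
        n_q = int(round(post_question_rate * n_items))
        pq = np.zeros(n_items, dtype=bool)
        pq[rng.choice(n_items, size=n_q, replace=False)] = True
        for i in range(n_items):
            rows.append(
                {
                    "subject": f"s{s:03d}",
                    "item": f"i{i:03d}",
                    "condition": conditions[i],
                    "trial_order": int(order[i]),
                    "post_question": bool(pq[i]),
                }
            )
    return DesignLayout(n_subjects=n_subjects, n_items=n_items, table=pd.DataFrame(rows))


# Dirichlet-categorical profiles calibrated (Monte Carlo) so that sample
# entropies of 30-respondent sets land near the two-level constraint
# targets of 0.68 (strong) and 2.44 (weak) bits.
CLOZE_PROFILES = {
    "strong": {"vocab_size": 8, "concentration": 0.06},
    "weak": {"vocab_size": 12, "concentration": 0.53},
}


def generate_cloze_responses(
    condition_profile: str,
    n_respondents: int = 30,
    vocab_size: int | None = None,
    concentration: float | None = None,
    seed: int = 0,
    *,
    item_id: str = "",
    condition_label: str = "",
) -> ClozeResponseSet:
    """Draw a response set from a Dirichlet-categorical law."""
    if condition_profile not in CLOZE_PROFILES:
        raise ValueError(f"unknown profile {condition_profile!r}")
    if n_respondents < 2:
        raise ValueError("n_respondents must be at least 2")
    prof = CLOZE_PROFILES[condition_profile]
    vocab_size = vocab_size or prof["vocab_size"]
    concentration = concentration if concentration is not None else prof["concentration"]
    if vocab_size < 2:
        raise ValueError("vocab_size must be at least 2")
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.full(vocab_size, concentration))
    draws = rng.choice(vocab_size, size=n_respondents, p=p)
    tokens = [f"w{k:02d}" for k in draws]
    return ClozeResponseSet(
        item_id=item_id, condition_label=condition_label, responses=tokens
    )


def generate_predictors(
    n_items: int, n_respondents: int = 30, seed: int = 0
) -> pd.DataFrame:
    """Full predictor table over all (item, condition) cells.

    Conditions a/b use the strong profile, c/d the weak one. The condition-a
    target is the modal completion (high cloze); b/c/d targets are the least
    frequent observed completion (low cloze), as in the two-by-two
    constraint-by-predictability design this emulates.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_items * 4)
    response_sets = []
    targets = {}
    k = 0
    for i in range(n_items):
        item = f"i{i:03d}"
        for cond in CONDITIONS:
            profile = "strong" if cond in ("a", "b") else "weak"
            rs = generate_cloze_responses(
                profile, n_respondents, seed=int(seeds[k]),
                item_id=item, condition_label=cond,
            )
            counts = rs.counts
            if cond == "a":
                target = max(counts, key=lambda t: (counts[t], t))
            else:
                # low-cloze target: rarest observed completion, or an
                # unobserved one when every observed type is frequent
                target = min(counts, key=lambda t: (counts[t], t))
                if counts[target] > max(1, 0.15 * n_respondents):
                    target = "unseen"
            response_sets.append(rs)
            targets[(item, cond)] = target
            k += 1
    return build_predictor_table(response_sets, targets)


def generate_trial_amplitudes(
    truth: TruthParams, layout: DesignLayout, predictors: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Trial table from the generative hierarchical model.

    amplitude = alpha + b_c * entropy_centered + b_p * log2cloze_centered
                + u_subject . [1, entropy_c, cloze_c] + w_item + eps,
    with u_subject ~ MVN(0, diag(sigma) rho diag(sigma)). Predictors are
    centred over the rows of the merged layout.
    """
    tab = layout.table.merge(
        predictors[["item_id", "condition", "entropy_bits", "log2_cloze_smoothed"]],
        left_on=["item", "condition"],
        right_on=["item_id", "condition"],
        how="left",
        validate="many_to_one",
    )
    if tab["entropy_bits"].isna().any():
        missing = tab.loc[tab["entropy_bits"].isna(), ["item", "condition"]]
        raise ValueError(f"predictors missing for: {missing.drop_duplicates().values.tolist()[:10]}")
    tab = tab.drop(columns=["item_id"])
    tab["entropy_centered"] = center_predictor(tab["entropy_bits"].to_numpy())
    tab["log2_cloze_centered"] = center_predictor(tab["log2_cloze_smoothed"].to_numpy())

    rng = np.random.default_rng(seed)
    cov = np.diag(truth.sigma_subject) @ truth.rho @ np.diag(truth.sigma_subject)
    # diag(sigma) L_rho gives an exact matrix square root even when some
    # sigma are exactly zero (cholesky of the product would need jitter)
    chol = np.diag(truth.sigma_subject) @ np.linalg.cholesky(
        truth.rho + 1e-12 * np.eye(3)
    )
    subjects = sorted(tab["subject"].unique())
    items = sorted(tab["item"].unique())
    u = rng.standard_normal((len(subjects), 3)) @ chol.T
    w = rng.normal(0.0, truth.sigma_item, size=len(items)) if truth.sigma_item > 0 else np.zeros(len(items))
    s_idx = tab["subject"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    i_idx = tab["item"].map({it: i for i, it in enumerate(items)}).to_numpy()

    z = np.column_stack(
        [np.ones(len(tab)), tab["entropy_centered"], tab["log2_cloze_centered"]]
    )
    mu = (
        truth.alpha
        + truth.beta_constraint * tab["entropy_centered"].to_numpy()
        + truth.beta_predictability * tab["log2_cloze_centered"].to_numpy()
        + np.einsum("na,na->n", z, u[s_idx])
        + w[i_idx]
    )
    eps = (
        rng.normal(0.0, truth.sigma_residual, size=len(tab))
        if truth.sigma_residual > 0
        else np.zeros(len(tab))
    )
    tab["amplitude"] = mu + eps
    return tab


# ---------------------------------------------------------------------------
# raw epochs


def generate_epochs(
    layout: DesignLayout,
    component_spec: list[dict],
    artifact_spec: dict | None = None,
    srate: float = 512.0,
    window_ms: tuple[float, float] = (-200.0, 1200.0),
    seed: int = 0,
    noise_sd: float = 0.0,
):
    """Raw epochs with flat component templates and optional artifacts.

    Each ``component_spec`` entry is a dict with keys ``name``,
    ``electrodes``, ``window_ms`` and ``amplitude`` (scalar, mapping
    condition -> uV, or per-trial array). The pre-noise window means are
    returned alongside so recovery checks can be exact. Injected blink
    (frontal, > 100 uV peak) and step (single-sample offset) artifacts
    exceed the rejection thresholds by construction.

    Returns ``(EpochSet, info)`` where ``info`` carries ``true_window_means``
    (trials x component DataFrame) and ``artifact_trials``.
    """
    if window_ms[0] > -200.0 or window_ms[1] < 1000.0:
        raise ValueError("epoch window must cover [-200, 1000] ms")
    artifact_spec = dict(artifact_spec or {})
    blink_rate = artifact_spec.get("blink_rate", 0.0)
    step_rate = artifact_spec.get("step_rate", 0.0)
    blink_amp = artifact_spec.get("blink_amplitude", 160.0)
    step_amp = artifact_spec.get("step_amplitude", 150.0)

    rng = np.random.default_rng(seed)
    trials = layout.table.reset_index(drop=True)
    n_trials = len(trials)
    s0, s1 = ms_to_sample_range(window_ms[0], window_ms[1], srate, 0)
    n_samples = s1 - s0
    time0 = -s0
    channels = list(DEFAULT_CHANNELS)
    data = np.zeros((n_trials, len(channels), n_samples))
    ch_idx = {c: i for i, c in enumerate(channels)}

    means = {}
    for comp in component_spec:
        amp = comp["amplitude"]
        if np.isscalar(amp):
            amps = np.full(n_trials, float(amp))
        elif isinstance(amp, dict):
            amps = trials["condition"].map(amp).to_numpy(dtype=float)
        else:
            amps = np.asarray(amp, dtype=float)
            if amps.shape != (n_trials,):
                raise ValueError(f"per-trial amplitudes for {comp['name']!r} have wrong length")
        c0, c1 = ms_to_sample_range(comp["window_ms"][0], comp["window_ms"][1], srate, time0)
        rows = [ch_idx[c] for c in comp["electrodes"]]
        data[:, np.array(rows)[:, None], np.arange(c0, c1)[None, :]] += amps[:, None, None]
        means[comp["name"]] = amps

    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)

    artifact = np.zeros(n_trials, dtype=bool)
    frontal = [ch_idx[c] for c in ("Fp1", "Fpz", "Fp2")]
    t = np.arange(n_samples) / srate * 1000.0  # ms from epoch start
    for i in range(n_trials):
        if rng.uniform() < blink_rate:
            center = rng.uniform(200, (n_samples / srate) * 1000.0 - 200)
            bump = blink_amp * np.exp(-0.5 * ((t - center) / 60.0) ** 2)
            data[i, frontal, :] += bump
            artifact[i] = True
        elif rng.uniform() < step_rate:
            pos = rng.integers(time0, n_samples - 10)
            chan = rng.integers(0, len(channels))
            data[i, chan, pos:] += step_amp
            artifact[i] = True

    epochs = EpochSet(data=data, srate=srate, time0=time0, channel_labels=channels)
    info = {
        "true_window_means": pd.DataFrame(means),
        "artifact_trials": artifact,
    }
    return epochs, info


# ---------------------------------------------------------------------------
# stop-signal sessions


def generate_stop_signal_session(
    true_ssrt: float,
    go_rt_distribution: tuple[float, float] = (900.0, 150.0),
    tracking: dict | None = None,
    n_trials: int = 96,
    seed: int = 0,
    p_stop: float = 0.25,
    go_omission_rate: float = 0.0,
    participant_id: str = "p000",
) -> StopSignalSession:
    """Independent-race simulation with the staircase tracking procedure.

    On a stop trial with delay SSD a response occurs iff the go finishing
    time is below SSD + true SSRT; the SSD then moves 'step' ms up after a
    successful stop and down after a failed one, clamped to [min, max].
    """
    if n_trials < 8:
        raise ValueError("n_trials must be at least 8")
    tracking = {
        "start": 250.0, "step": 50.0, "min": 50.0, "max": 1000.0,
        **(tracking or {}),
    }
    rng = np.random.default_rng(seed)
    mu, sd = go_rt_distribution
    ssd = float(tracking["start"])
    go_trials: list[float | None] = []
    stop_trials: list[tuple[float, bool, float | None]] = []
    is_stop = rng.uniform(size=n_trials) < p_stop
    for k in range(n_trials):
        rt = max(float(rng.normal(mu, sd)), 1.0)
        if is_stop[k]:
            responded = rt < ssd + true_ssrt
            stop_trials.append((ssd, responded, rt if responded else None))
            ssd += -tracking["step"] if responded else tracking["step"]
            ssd = float(np.clip(ssd, tracking["min"], tracking["max"]))
        else:
            if rng.uniform() < go_omission_rate:
                go_trials.append(None)
            else:
                go_trials.append(rt)
    return StopSignalSession(
        participant_id=participant_id, go_trials=go_trials, stop_trials=stop_trials
    )


# ---------------------------------------------------------------------------
# convenience


def simulate_trial_table(
    truth: TruthParams,
    n_subjects: int,
    n_items: int,
    seed: int = 0,
    n_respondents: int = 30,
):
    """Design + cloze predictors + amplitudes in one seeded call."""
    ss = np.random.SeedSequence(seed)
    s_design, s_cloze, s_amp = ss.spawn(3)
    layout = build_design(n_subjects, n_items, seed=int(s_design.generate_state(1)[0]))
    predictors = generate_predictors(
        n_items, n_respondents=n_respondents, seed=int(s_cloze.generate_state(1)[0])
    )
    table = generate_trial_amplitudes(
        truth, layout, predictors, seed=int(s_amp.generate_state(1)[0])
    )
    return layout, predictors, table
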