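"""Synthetic study generator with planted, recoverable structure.

Builds groups of classmates with a friendship network, questionnaire
responses driven by latent affect/relationship states, and coupled cardiac
beat series: each subject's instantaneous heart rate carries HF (respiratory
sinus arrhythmia) and LF oscillations plus pink noise, and each dyad shares
band-limited drive signals whose weights encode planted friendship and
affect effects. Beats are emitted by integrate-and-fire over the rate, so
the whole analysis chain can be scored against known ground truth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .measures import AffectGridValue
from .preprocess import RRSeries

__all__ = [
    "CardiacConfig",
    "CouplingConfig",
    "EffectConfig",
    "CohortConfig",
    "Roster",
    "Questionnaires",
    "SyntheticTruth",
    "generate_roster",
    "generate_questionnaires",
    "generate_coupled_rr",
    "score_recovery",
]

PHASE_GAP_S = 10.0


@dataclass(frozen=True)
class CardiacConfig:
    mean_hr_bpm: float = 85.0
    sd_hr_bpm: float = 7.0
    rsa_freq_hz: float = 0.25
    rsa_amp: float = 1.5
    lf_freq_hz: float = 0.1
    lf_amp: float = 1.5
    noise_sd: float = 1.2
    hf_drive_band: tuple[float, float] = (0.18, 0.35)
    lf_drive_band: tuple[float, float] = (0.04, 0.11)
    grid_hz: float = 4.0
    spike_rate: float = 0.0       # per-beat probability of an rr spike
    dropout_rate: float = 0.0     # per-beat probability of starting a dropout


@dataclass(frozen=True)
class CouplingConfig:
    """Dyadic shared-drive weights.

    Each subject's per-band drive is the kappa-weighted mix of the shared
    signals of all dyads they belong to, normalized by the dyad count
    against the band's reference kappa at amplitude ``amp_lf``/``amp_hf``
    bpm: belonging to many dyads does not inflate a subject's band power,
    but a strongly coupled dyad raises the shared band power of its two
    members. ``expected_*`` record the fitted z-scale effects the default
    generator was calibrated to induce; they are recovery targets, not
    inputs to the signal.
    """

    kappa_lf_friend: float = 1.22
    kappa_lf_nonfriend: float = 0.9
    kappa_hf_base: float = 1.2
    beta_hf_negaffect: float = 0.38
    amp_lf: float = 2.5
    amp_hf: float = 2.5
    expected_lf_mutual_z: float = 0.24
    expected_hf_valence_z: float = -0.22


@dataclass(frozen=True)
class EffectConfig:
    """Planted questionnaire-level effects."""

    closeness_friend: float = 1.5     # IOS shift for mutual friends
    closeness_one_sided: float = 0.8
    liking_friend: float = 0.5
    estimate_noise_sd: float = 0.8    # noise on affect estimates
    ios_noise_sd: float = 1.0
    liking_noise_sd: float = 0.5


@dataclass(frozen=True)
class CohortConfig:
    n_groups: int = 10
    group_size_range: tuple[int, int] = (4, 6)
    p_mutual_friendship: float = 0.28
    p_one_sided: float = 0.14
    gender_ratio: float = 0.5
    seed: int = 0
    phase_durations: dict = field(default_factory=lambda: {
        "baseline": 300.0, "story": 540.0, "discussion": 600.0})
    cardiac: CardiacConfig = CardiacConfig()
    coupling: CouplingConfig = CouplingConfig()
    effects: EffectConfig = EffectConfig()

    def __post_init__(self) -> None:
        lo, hi = self.group_size_range
        if not (2 <= lo <= hi <= 12):
            raise ValueError("group_size_range must lie within [2, 12]")
        for p in (self.p_mutual_friendship, self.p_one_sided, self.gender_ratio):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def phase_marks(self) -> dict[str, tuple[float, float]]:
        marks = {}
        t = 0.0
        for label in ("baseline", "story", "discussion"):
            d = float(self.phase_durations[label])
            marks[label] = (t, t + d)
            t += d + PHASE_GAP_S
        return marks


@dataclass
class Roster:
    subjects: pd.DataFrame            # subject_id, group_id, gender, age, ...
    friendship: dict[tuple[str, str], str]   # unordered pair -> status
    nominations: dict[str, list[str]]

    def dyads(self) -> list[tuple[str, str, str]]:
        """(member_a, member_b, group_id) for every within-group pair."""
        out = []
        for group_id, grp in self.subjects.groupby("group_id"):
            ids = sorted(grp["subject_id"])
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    out.append((ids[i], ids[j], group_id))
        return out


@dataclass
class Questionnaires:
    ios: dict                          # rater -> target -> timepoint -> 0-6
    liking: dict                       # rater -> target -> timepoint -> items
    self_affect: dict[str, AffectGridValue]
    estimates: dict[tuple[str, str], AffectGridValue]
    group_feelings: pd.DataFrame       # subject_id, safe, content, stressed
    latent_valence: dict[str, float]
    latent_arousal: dict[str, float]


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery without re-reading the config."""

    coupling_hf: dict[str, float]      # dyad_id -> kappa
    coupling_lf: dict[str, float]
    planted: dict[str, float]          # term name -> planted effect target
    subject_params: dict[str, dict]

    def to_json(self, path) -> None:
        payload = {
            "coupling_hf": self.coupling_hf,
            "coupling_lf": self.coupling_lf,
            "planted": self.planted,
            "subject_params": self.subject_params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _dyad_id(a: str, b: str) -> str:
    a, b = sorted((a, b))
    return f"{a}__{b}"


# ---------------------------------------------------------------------------
# roster

def generate_roster(config: CohortConfig) -> Roster:
    """Groups of classmates with genders, anthropometrics, circular seating
    and a friendship network (mutual with ``p_mutual_friendship``, one-sided
    with ``p_one_sided`` per unordered pair)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    lo, hi = config.group_size_range
    rows = []
    friendship: dict[tuple[str, str], str] = {}
    nominations: dict[str, list[str]] = {}
    for g in range(config.n_groups):
        size = int(rng.integers(lo, hi + 1))
        group_id = f"g{g:03d}"
        ids = [f"{group_id}s{k}" for k in range(size)]
        seats = rng.permutation(size)
        for k, sid in enumerate(ids):
            height = float(np.clip(rng.normal(1.50, 0.08), 1.25, 1.80))
            bmi = float(np.clip(rng.normal(17.8, 2.4), 13.0, 30.0))
            rows.append({
                "subject_id": sid,
                "group_id": group_id,
                "gender": "female" if rng.random() < config.gender_ratio else "male",
                "age": float(np.clip(rng.normal(11.32, 0.69), 10.0, 13.0)),
                "height_m": height,
                "weight_kg": bmi * height**2,
                "seat_position": int(seats[k]),
            })
            nominations[sid] = []
        for i in range(size):
            for j in range(i + 1, size):
                a, b = ids[i], ids[j]
                u = rng.random()
                if u < config.p_mutual_friendship:
                    status = "mutual"
                    nominations[a].append(b)
                    nominations[b].append(a)
                elif u < config.p_mutual_friendship + config.p_one_sided:
                    status = "one_sided"
                    if rng.random() < 0.5:
                        nominations[a].append(b)
                    else:
                        nominations[b].append(a)
                else:
                    status = "none"
                friendship[tuple(sorted((a, b)))] = status
    return Roster(subjects=pd.DataFrame(rows), friendship=friendship,
                  nominations=nominations)


# ---------------------------------------------------------------------------
# questionnaires

def _discretize_grid(lat: float) -> int:
    """Map a latent standard-normal coordinate onto the 1-3 grid (tertiles)."""
    if lat < -0.4307:
        return 1
    if lat > 0.4307:
        return 3
    return 2


def generate_questionnaires(
    roster: Roster, config: CohortConfig
) -> Questionnaires:
    """Questionnaire tables driven by latent states.

    Self-affect comes from a latent bivariate (valence, arousal) state per
    subject; estimates of others add ``estimate_noise_sd`` to the target's
    latent state before discretization, so zero noise yields perfect
    empathic accuracy. Closeness and liking shift with friendship status by
    the planted effect sizes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    eff = config.effects
    lat_v: dict[str, float] = {}
    lat_a: dict[str, float] = {}
    feelings = []
    for sid in roster.subjects["subject_id"]:
        lat_v[sid] = float(rng.normal(0.0, 1.0))
        lat_a[sid] = float(rng.normal(0.0, 1.0))
        feelings.append({
            "subject_id": sid,
            "safe": int(rng.integers(1, 5)),
            "content": int(rng.integers(1, 5)),
            "stressed": int(rng.integers(1, 5)),
        })

    self_affect = {
        sid: AffectGridValue(
            valence=_discretize_grid(lat_v[sid]),
            arousal=_discretize_grid(lat_a[sid]),
            timepoint="T1", reporter_id=sid, target_id=sid)
        for sid in lat_v
    }

    ios: dict = {}
    liking: dict = {}
    estimates: dict = {}
    for a, b, _g in roster.dyads():
        status = roster.friendship[(a, b)]
        for rater, target in ((a, b), (b, a)):
            shift = {"mutual": eff.closeness_friend,
                     "one_sided": eff.closeness_one_sided,
                     "none": 0.0}[status]
            ios.setdefault(rater, {})[target] = {
                tp: float(np.clip(round(rng.normal(3.0 + shift, eff.ios_noise_sd)),
                                  0, 6))
                for tp in ("T0", "T1", "T2")
            }
            like_shift = eff.liking_friend if status == "mutual" else 0.0
            liking.setdefault(rater, {})[target] = {}
            for tp in ("T0", "T4"):
                base = rng.normal(3.0 + like_shift, eff.liking_noise_sd)
                items = {}
                from .measures import LIKING_ITEMS, REVERSE_ITEMS
                for item in LIKING_ITEMS:
                    intended = float(np.clip(round(base + rng.normal(0, 0.5)), 1, 4))
                    items[item] = 5.0 - intended if item in REVERSE_ITEMS else intended
                liking[rater][target][tp] = items
            estimates[(rater, target)] = AffectGridValue(
                valence=_discretize_grid(
                    lat_v[target] + rng.normal(0, eff.estimate_noise_sd)
                    if eff.estimate_noise_sd > 0 else lat_v[target]),
                arousal=_discretize_grid(
                    lat_a[target] + rng.normal(0, eff.estimate_noise_sd)
                    if eff.estimate_noise_sd > 0 else lat_a[target]),
                timepoint="T1", reporter_id=rater, target_id=target)

    return Questionnaires(
        ios=ios, liking=liking, self_affect=self_affect, estimates=estimates,
        group_feelings=pd.DataFrame(feelings),
        latent_valence=lat_v, latent_arousal=lat_a,
    )


# ---------------------------------------------------------------------------
# coupled cardiac series

def _band_noise(rng: np.random.Generator, n: int, dt: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` (Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=dt)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, dt: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=dt)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _integrate_and_fire(rate_bpm: np.ndarray, dt: float) -> np.ndarray:
    """Beat times from an instantaneous rate: one beat per accumulated cycle."""
    if np.any(rate_bpm <= 0):
        raise ValueError("instantaneous rate went non-positive; config rejected")
    t = np.arange(rate_bpm.size) * dt
    phase = np.concatenate(([0.0], np.cumsum(rate_bpm) * dt / 60.0))
    t_edges = np.concatenate((t, [t[-1] + dt]))
    n_beats = int(np.floor(phase[-1]))
    targets = np.arange(1, n_beats + 1, dtype=float)
    return np.interp(targets, phase, t_edges)


def _inject_artifacts(times: np.ndarray, rr: np.ndarray,
                      rng: np.random.Generator,
                      spike_rate: float, dropout_rate: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Multiply random beats' rr by a spike factor and delete dropout runs
    (timestamps of surviving beats are kept, so dropouts leave real gaps)."""
    rr = rr.copy()
    n = rr.size
    if spike_rate > 0:
        hit = rng.random(n) < spike_rate
        rr[hit] *= rng.uniform(1.5, 2.2, size=int(hit.sum()))
    keep = np.ones(n, dtype=bool)
    if dropout_rate > 0:
        i = 0
        while i < n:
            if keep[i] and rng.random() < dropout_rate:
                run = int(rng.integers(3, 9))
                keep[i:i + run] = False
                i += run
            else:
                i += 1
    return times[keep], rr[keep]


def generate_coupled_rr(
    roster: Roster,
    quest: Questionnaires,
    config: CohortConfig,
) -> tuple[dict[str, RRSeries], SyntheticTruth]:
    """Per-subject beat series with dyad-shared band-limited drives.

    LF coupling weight is ``kappa_lf_friend`` for mutual friendships and
    ``kappa_lf_nonfriend`` otherwise; HF coupling is
    ``kappa_hf_base + beta_hf_negaffect * negative_affect`` where negative
    affect is the (sign-flipped) mean latent valence of the dyad. Subjects
    sum the drives of every dyad they belong to on top of their own
    oscillatory base process.
    """
    card = config.cardiac
    coup = config.coupling
    marks = config.phase_marks()
    total_s = max(end for _s, end in marks.values())
    dt = 1.0 / card.grid_hz
    n = int(np.ceil(total_s / dt)) + 1

    ss = np.random.SeedSequence([config.seed, 37])
    rng_master = np.random.default_rng(ss)

    subjects = list(roster.subjects["subject_id"])
    base_rates: dict[str, np.ndarray] = {}
    subject_params: dict[str, dict] = {}
    t_grid = np.arange(n) * dt
    for sid in subjects:
        r = np.random.default_rng(np.random.SeedSequence(
            [config.seed, 37, zlib.crc32(sid.encode())]))
        mean_hr = r.normal(card.mean_hr_bpm, card.sd_hr_bpm)
        f_rsa = card.rsa_freq_hz * (1.0 + r.normal(0, 0.05))
        f_lf = card.lf_freq_hz * (1.0 + r.normal(0, 0.05))
        ph1, ph2 = r.uniform(0, 2 * np.pi, 2)
        rate = (mean_hr
                + card.rsa_amp * np.sin(2 * np.pi * f_rsa * t_grid + ph1)
                + card.lf_amp * np.sin(2 * np.pi * f_lf * t_grid + ph2)
                + card.noise_sd * _pink_noise(r, n, dt))
        base_rates[sid] = rate
        subject_params[sid] = {"mean_hr": float(mean_hr),
                               "f_rsa": float(f_rsa), "f_lf": float(f_lf)}

    coupling_hf: dict[str, float] = {}
    coupling_lf: dict[str, float] = {}
    drives: dict[str, dict[str, list[tuple[float, np.ndarray]]]] = {
        sid: {"lf": [], "hf": []} for sid in subjects}
    for a, b, _g in roster.dyads():
        did = _dyad_id(a, b)
        status = roster.friendship[(a, b)]
        k_lf = (coup.kappa_lf_friend if status == "mutual"
                else coup.kappa_lf_nonfriend)
        negaffect = -(quest.latent_valence[a] + quest.latent_valence[b]) / 2.0
        k_hf = max(0.0, coup.kappa_hf_base + coup.beta_hf_negaffect * negaffect)
        coupling_lf[did] = float(k_lf)
        coupling_hf[did] = float(k_hf)
        r = np.random.default_rng(np.random.SeedSequence(
            [config.seed, 53, zlib.crc32(did.encode())]))
        z_lf = _band_noise(r, n, dt, card.lf_drive_band)
        z_hf = _band_noise(r, n, dt, card.hf_drive_band)
        for sid in (a, b):
            drives[sid]["lf"].append((k_lf, z_lf))
            drives[sid]["hf"].append((k_hf, z_hf))

    # mix each subject's dyad drives, normalized by dyad count against the
    # band's reference kappa: belonging to many dyads does not inflate a
    # subject's band power, but a strongly coupled dyad still raises the
    # shared (and thus cross-wavelet) power of its two members
    ref = {"lf": max(coup.kappa_lf_nonfriend, 1e-6),
           "hf": max(coup.kappa_hf_base, 1e-6)}
    for sid in subjects:
        for band, amp in (("lf", coup.amp_lf), ("hf", coup.amp_hf)):
            parts = drives[sid][band]
            if not parts:
                continue
            scale = amp / (ref[band] * np.sqrt(len(parts)))
            mix = sum(k * z for k, z in parts) * scale
            base_rates[sid] = base_rates[sid] + mix

    series: dict[str, RRSeries] = {}
    for sid in subjects:
        beat_times = _integrate_and_fire(base_rates[sid], dt)
        rr = np.diff(beat_times) * 1000.0
        times = beat_times[1:]
        if card.spike_rate > 0 or card.dropout_rate > 0:
            r = np.random.default_rng(np.random.SeedSequence(
                [config.seed, 71, zlib.crc32(sid.encode())]))
            times, rr = _inject_artifacts(times, rr, r,
                                          card.spike_rate, card.dropout_rate)
        series[sid] = RRSeries(
            subject_id=sid, session_id="synthetic",
            times_s=times, rr_ms=rr, phase_marks=marks,
        )

    truth = SyntheticTruth(
        coupling_hf=coupling_hf,
        coupling_lf=coupling_lf,
        planted={
            "kappa_lf_friend": coup.kappa_lf_friend,
            "kappa_lf_nonfriend": coup.kappa_lf_nonfriend,
            "kappa_hf_base": coup.kappa_hf_base,
            "beta_hf_negaffect": coup.beta_hf_negaffect,
            "expected_lf_mutual_z": coup.expected_lf_mutual_z,
            "expected_hf_valence_z": coup.expected_hf_valence_z,
        },
        subject_params=subject_params,
    )
    # silence unused-variable linters for rng_master: kept for future fields
    del rng_master
    return series, truth


# ---------------------------------------------------------------------------
# recovery scoring

def score_recovery(
    fits: list,
    truth_terms: dict[str, float],
) -> pd.DataFrame:
    """Bias, RMSE, 95%-interval coverage and sign-detection rate per term.

    ``fits`` is a list of :class:`~peersync.models.MixedModelFit` from
    replicate cohorts; ``truth_terms`` maps coefficient term names to their
    planted values (0 for null effects).
    """
    rows = []
    for term, true_val in truth_terms.items():
        ests, covers, signs = [], [], []
        for fit in fits:
            tab = fit.coefficients.set_index("term")
            if term not in tab.index:
                raise ValueError(f"term {term!r} missing from a fit")
            est = tab.loc[term, "estimate"]
            lo, hi = tab.loc[term, "ci_low"], tab.loc[term, "ci_high"]
            p = tab.loc[term, "p"]
            ests.append(est)
            covers.append(lo <= true_val <= hi)
            if true_val != 0:
                signs.append(bool(np.sign(est) == np.sign(true_val) and p < 0.05))
        ests = np.asarray(ests, dtype=float)
        rows.append({
            "term": term,
            "true": true_val,
            "bias": float(ests.mean() - true_val),
            "rmse": float(np.sqrt(np.mean((ests - true_val) ** 2))),
            "coverage": float(np.mean(covers)),
            "sign_detection": float(np.mean(signs)) if signs else np.nan,
            "n_fits": len(fits),
        })
    return pd.DataFrame(rows)


def config_to_dict(config: CohortConfig) -> dict:
    return asdict(config)
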