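"""Synthetic multimodal MS cohorts with known, controllable class signal.

Real cohorts of this kind (longitudinal labs/vitals/medications, per-sequence
brain MRI, free-text encounter notes, per-visit EDSS) are private, so every
stage of the pipeline is exercised on generated patients whose ground-truth
signal is planted by construction:

* a designated subset of lab features is mean-shifted (in standardized units)
  for patients who go on to reach the EDSS milestone;
* medication administration rates differ by class;
* MRI volumes carry a class-dependent number of lesion-like hyperintense
  ellipsoidal blobs at recorded locations (so saliency maps can be scored
  against the planted masks);
* notes are drawn from class-conditional unigram distributions in which
  designated tokens are up-weighted for positives.

Setting all positive/negative parameters equal yields a null cohort in which
no classifier should beat chance.  Generation is fully deterministic given
``SignalSpec.seed``.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SignalSpec",
    "SyntheticPatient",
    "SyntheticCohort",
    "generate_cohort",
    "generate_volume",
    "generate_note",
    "default_vocab",
    "write_cohort",
]

#: MRI sequence identifiers in acquisition-contrast order.
ALL_SEQUENCES = ("t1_pre", "t1_post", "t2", "flair", "pd")

_EPOCH = dt.datetime(2014, 1, 1)


def default_vocab(size: int = 50) -> list[str]:
    """A small clinical-flavoured vocabulary for note generation."""
    stems = [
        "patient", "gait", "fatigue", "numbness", "vision", "tremor", "spasticity",
        "relapse", "lesion", "mri", "stable", "improved", "worsening", "weakness",
        "balance", "exam", "normal", "reflex", "sensory", "motor", "ambulation",
        "cane", "walker", "dose", "therapy", "infusion", "followup", "reports",
        "denies", "bladder", "cognition", "baseline", "flare", "steroid", "left",
        "right", "mild", "moderate", "severe", "unchanged", "progression",
        "assistance", "dizziness", "pain", "spasm", "neurology", "clinic",
        "review", "plan", "continue",
    ]
    vocab = stems[:size]
    i = 0
    while len(vocab) < size:
        vocab.append(f"term{i:03d}")
        i += 1
    return vocab


@dataclass
class SignalSpec:
    """Generative parameters of a synthetic cohort.

    Class-conditional parameters come in ``*_pos`` / ``*_neg`` pairs; equal
    pairs (and ``lab_shift=0``, unit note multipliers) define a null cohort.
    """

    n_patients: int = 300
    prevalence: float = 0.25
    lab_shift: float = 0.0
    n_shifted_lab_features: int = 3
    med_rate_pos: float = 0.3
    med_rate_neg: float = 0.3
    lesion_count_pos: float = 1.0
    lesion_count_neg: float = 1.0
    note_signal_tokens: dict[str, float] = field(default_factory=dict)
    visit_count_mean: float = 3.39
    followup_years_mean: float = 5.14
    milestone: float = 4.0
    n_lab_features: int = 14
    n_rare_lab_features: int = 2
    n_vital_features: int = 8
    n_med_features: int = 6
    sequences: tuple[str, ...] = ALL_SEQUENCES
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    note_length: int = 80
    vocab_size: int = 50
    missing_image_rate: float = 0.1
    missing_note_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.n_patients > 0 and not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        for name in ("med_rate_pos", "med_rate_neg", "missing_image_rate",
                     "missing_note_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("lesion_count_pos", "lesion_count_neg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.visit_count_mean < 1:
            raise ValueError("visit_count_mean must be at least 1")
        if self.n_shifted_lab_features > self.n_lab_features:
            raise ValueError("n_shifted_lab_features exceeds n_lab_features")
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape extents must be positive")
        for tok, mult in self.note_signal_tokens.items():
            if mult < 0:
                raise ValueError(f"note_signal_tokens[{tok!r}] must be non-negative")

    # feature schemas ------------------------------------------------------
    @property
    def lab_features(self) -> list[str]:
        return [f"lab_{i:02d}" for i in range(self.n_lab_features)]

    @property
    def shifted_lab_features(self) -> list[str]:
        return self.lab_features[: self.n_shifted_lab_features]

    @property
    def rare_lab_features(self) -> list[str]:
        return self.lab_features[self.n_lab_features - self.n_rare_lab_features:]

    @property
    def vital_features(self) -> list[str]:
        return [f"vital_{i:02d}" for i in range(self.n_vital_features)]

    @property
    def med_features(self) -> list[str]:
        return [f"med_{i:02d}" for i in range(self.n_med_features)]


@dataclass
class SyntheticPatient:
    patient_id: str
    label: int
    events: dict[str, pd.DataFrame]          # kind -> long-format event table
    visits: pd.DataFrame                     # visit_time, edss
    demographics: dict
    sessions: list[dict]                     # [{time, volumes{seq: arr}, blobs{seq: [...]}}]
    notes: list[tuple[str, str]]             # (encounter_id, text)


@dataclass
class SyntheticCohort:
    spec: SignalSpec
    patients: list[SyntheticPatient]

    def __len__(self):
        return len(self.patients)

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.patients], dtype=int)


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------


def generate_volume(lesion_count: int, shape: tuple[int, int, int],
                    rng: np.random.Generator) -> tuple[np.ndarray, list[dict]]:
    """Background noise plus ``lesion_count`` ellipsoidal hyperintense blobs.

    Returns the volume (intensities in [0, 1]) and a list of blob records
    ``{"center": (x, y, z), "semiaxes": (a, b, c)}`` for saliency scoring.
    """
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ValueError(f"volume extents must be positive, got {shape}")
    if lesion_count < 0:
        raise ValueError("lesion_count must be non-negative")
    vol = rng.normal(0.2, 0.04, size=shape)
    blobs: list[dict] = []
    grid = np.indices(shape)
    for _ in range(int(lesion_count)):
        center = np.array([rng.uniform(0.15 * s, 0.85 * s) for s in shape])
        semiaxes = np.array([rng.uniform(1.5, max(2.0, 0.12 * s)) for s in shape])
        dist2 = sum(((grid[a] - center[a]) / semiaxes[a]) ** 2 for a in range(3))
        intensity = rng.uniform(0.7, 1.0)
        vol = np.where(dist2 <= 1.0, np.maximum(vol, intensity), vol)
        blobs.append({"center": tuple(center), "semiaxes": tuple(semiaxes)})
    return np.clip(vol, 0.0, 1.0), blobs


def blob_mask(shape: tuple[int, int, int], blobs: list[dict]) -> np.ndarray:
    """Boolean mask of planted blob support."""
    mask = np.zeros(shape, dtype=bool)
    grid = np.indices(shape)
    for blob in blobs:
        c, s = np.asarray(blob["center"]), np.asarray(blob["semiaxes"])
        dist2 = sum(((grid[a] - c[a]) / s[a]) ** 2 for a in range(3))
        mask |= dist2 <= 1.0
    return mask


# ---------------------------------------------------------------------------
# Notes
# ---------------------------------------------------------------------------


def generate_note(label: int, vocab: list[str], signal_tokens: dict[str, float],
                  length: int, rng: np.random.Generator) -> str:
    """Draw a note from the class-conditional unigram mixture.

    Negatives use a uniform distribution over ``vocab``; positives multiply
    the probability of each token in ``signal_tokens`` by its multiplier and
    renormalize.
    """
    if not vocab:
        raise ValueError("vocab must be non-empty")
    if length < 1:
        raise ValueError("note length must be at least 1")
    probs = np.ones(len(vocab))
    if label:
        for tok, mult in signal_tokens.items():
            if tok in vocab:
                probs[vocab.index(tok)] *= mult
    probs = probs / probs.sum()
    idx = rng.choice(len(vocab), size=length, p=probs)
    return " ".join(vocab[i] for i in idx)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def _edss_trajectory(label: int, n_visits: int, theta: float,
                     rng: np.random.Generator) -> np.ndarray:
    """EDSS per visit, consistent with the milestone rule (last visit > theta
    iff positive; EDSS milestone strict per the label-derivation contract)."""
    if label:
        start = rng.uniform(1.0, theta)
        end = rng.uniform(theta + 0.5, min(theta + 4.0, 9.5))
    else:
        start = rng.uniform(0.0, max(theta - 1.5, 0.5))
        end = rng.uniform(start, theta - 0.25) if theta > 0.5 else start
    traj = np.linspace(start, end, n_visits)
    if n_visits > 2:
        traj[1:-1] += rng.normal(0.0, 0.3, size=n_visits - 2)
    traj = np.clip(traj, 0.0, 9.5)
    traj[0] = start
    traj[-1] = end  # target endpoint fixed last so the label rule is exact
    return np.round(traj * 2) / 2  # EDSS is recorded in half-point steps


def _patient_events(spec: SignalSpec, label: int, encounters: list[dict],
                    rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    base_obs_rate = 0.7
    rows: dict[str, list] = {"lab": [], "vital": [], "medication": []}
    for enc in encounters:
        start, end, enc_id = enc["start"], enc["end"], enc["id"]
        span = (end - start).total_seconds()

        def obs_time():
            return start + dt.timedelta(seconds=float(rng.uniform(0, span)))

        for feat in spec.lab_features:
            rate = 0.05 if feat in spec.rare_lab_features else base_obs_rate
            n_obs = rng.binomial(2, rate)
            shift = spec.lab_shift if (label and feat in spec.shifted_lab_features) else 0.0
            for _ in range(n_obs):
                rows["lab"].append(
                    (enc_id, start, end, obs_time(), feat, rng.normal(shift, 1.0))
                )
        for feat in spec.vital_features:
            for _ in range(rng.binomial(2, base_obs_rate)):
                rows["vital"].append(
                    (enc_id, start, end, obs_time(), feat, rng.normal(0.0, 1.0))
                )
        rate = spec.med_rate_pos if label else spec.med_rate_neg
        for feat in spec.med_features:
            if rng.random() < rate:
                rows["medication"].append(
                    (enc_id, start, end, obs_time(), feat, 1.0)
                )
    cols = ["encounter_id", "encounter_start", "encounter_end", "obs_time",
            "feature", "value"]
    return {kind: pd.DataFrame(r, columns=cols) for kind, r in rows.items()}


def generate_cohort(spec: SignalSpec) -> SyntheticCohort:
    """Generate a deterministic multimodal cohort from a :class:`SignalSpec`."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    vocab = default_vocab(spec.vocab_size)
    patients: list[SyntheticPatient] = []
    for i in range(spec.n_patients):
        pid = f"p{i:04d}"
        label = int(rng.random() < spec.prevalence)

        # visits: 1 + Poisson keeps the minimum-one-visit guarantee
        n_visits = 1 + rng.poisson(max(spec.visit_count_mean - 1.0, 0.0))
        if n_visits == 1:
            offsets = np.array([0.0])
        else:
            span_years = rng.exponential(spec.followup_years_mean)
            offsets = np.sort(rng.uniform(0.0, span_years * 365.25, size=n_visits))
            offsets[0] = 0.0
        first = _EPOCH + dt.timedelta(days=float(rng.uniform(0, 365)))
        encounters = []
        for v, off in enumerate(offsets):
            start = first + dt.timedelta(days=float(off),
                                         hours=float(rng.uniform(7, 15)))
            duration = dt.timedelta(hours=float(rng.uniform(1.0, 8.0)))
            encounters.append({"id": f"{pid}_e{v:02d}", "start": start,
                               "end": start + duration})

        edss = _edss_trajectory(label, n_visits, spec.milestone, rng)
        visits = pd.DataFrame({
            "visit_time": [e["start"] for e in encounters],
            "edss": edss,
        })
        events = _patient_events(spec, label, encounters, rng)

        demographics = {
            "race": rng.choice(["white", "black"], p=[0.66, 0.34]),
            "ethnicity": rng.choice(["hispanic", "not_hispanic"], p=[0.33, 0.67]),
            "sex": rng.choice(["female", "male"], p=[0.78, 0.22]),
            "age": float(np.clip(rng.normal(43.6, 11.2), 19.0, 71.0)),
        }

        sessions: list[dict] = []
        if rng.random() >= spec.missing_image_rate:
            n_sessions = 1 + rng.poisson(0.2)
            session_encs = sorted(
                rng.choice(len(encounters), size=min(n_sessions, len(encounters)),
                           replace=False)
            )
            mean_count = spec.lesion_count_pos if label else spec.lesion_count_neg
            for si in session_encs:
                volumes, blobs = {}, {}
                for seq in spec.sequences:
                    count = rng.poisson(mean_count)
                    vol, blob_list = generate_volume(count, spec.volume_shape, rng)
                    volumes[seq] = vol.astype(np.float32)
                    blobs[seq] = blob_list
                sessions.append({"time": encounters[si]["start"],
                                 "volumes": volumes, "blobs": blobs})

        notes: list[tuple[str, str]] = []
        if rng.random() >= spec.missing_note_rate:
            for enc in encounters:
                notes.append((
                    enc["id"],
                    generate_note(label, vocab, spec.note_signal_tokens,
                                  spec.note_length, rng),
                ))

        patients.append(SyntheticPatient(
            patient_id=pid, label=label, events=events, visits=visits,
            demographics=demographics, sessions=sessions, notes=notes,
        ))
    return SyntheticCohort(spec=spec, patients=patients)


def null_spec(**overrides) -> SignalSpec:
    """A spec whose class-conditional parameters are all equal (no signal)."""
    base = dict(lab_shift=0.0, med_rate_pos=0.3, med_rate_neg=0.3,
                lesion_count_pos=1.0, lesion_count_neg=1.0,
                note_signal_tokens={})
    base.update(overrides)
    return SignalSpec(**base)


# ---------------------------------------------------------------------------
# On-disk layout (what the preprocessing pipeline reads)
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write a cohort in the pipeline's input layout: long-format CSV event
    tables, a visits/EDSS CSV, a demographics CSV, NIfTI volumes with a
    manifest, and UTF-8 note files with a manifest."""
    import nibabel as nib

    out = Path(out_dir)
    (out / "notes").mkdir(parents=True, exist_ok=True)
    (out / "images").mkdir(parents=True, exist_ok=True)

    event_frames = {k: [] for k in ("lab", "vital", "medication")}
    visit_rows, demo_rows, note_manifest, image_manifest = [], [], [], []
    for p in cohort.patients:
        for kind, df in p.events.items():
            if df.empty:
                continue
            df = df.copy()
            df.insert(0, "patient_id", p.patient_id)
            event_frames[kind].append(df)
        for _, row in p.visits.iterrows():
            visit_rows.append((p.patient_id, row.visit_time, row.edss))
        demo_rows.append({"patient_id": p.patient_id, **p.demographics})
        for enc_id, text in p.notes:
            path = out / "notes" / f"{enc_id}.txt"
            path.write_text(text, encoding="utf-8")
            note_manifest.append((p.patient_id, enc_id, str(path.relative_to(out))))
        for si, sess in enumerate(p.sessions):
            for seq, vol in sess["volumes"].items():
                rel = f"images/{p.patient_id}_s{si}_{seq}.nii.gz"
                nib.save(nib.Nifti1Image(vol.astype(np.float32), np.eye(4)), out / rel)
                image_manifest.append((p.patient_id, sess["time"], seq, rel))

    for kind, frames in event_frames.items():
        df = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["patient_id", "encounter_id",
                                         "encounter_start", "encounter_end",
                                         "obs_time", "feature", "value"]))
        df.to_csv(out / f"{kind}.csv", index=False)
    pd.DataFrame(visit_rows, columns=["patient_id", "visit_time", "edss"]).to_csv(
        out / "visits.csv", index=False)
    pd.DataFrame(demo_rows).to_csv(out / "demographics.csv", index=False)
    pd.DataFrame(note_manifest, columns=["patient_id", "encounter_id", "path"]).to_csv(
        out / "notes_manifest.csv", index=False)
    pd.DataFrame(image_manifest,
                 columns=["patient_id", "session_time", "sequence", "path"]).to_csv(
        out / "image_manifest.csv", index=False)
    spec_dict = dataclasses.asdict(cohort.spec)
    (out / "spec.json").write_text(_json_dumps(spec_dict), encoding="utf-8")


def _json_dumps(obj) -> str:
    import json

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(type(o))

    return json.dumps(obj, indent=2, default=default)
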