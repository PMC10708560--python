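"""Labeled synthetic dataset builders and the resample/segment preprocessor.

Three simulated corpora are produced, mirroring a study design with
per-subject (Fc, Fr) draws and a sweep of noise environments:

* a regression set: subjects in the normal physiological range
  (Fc in [0.83, 2] Hz, Fr in [0.16, 0.33] Hz), each observed at every SNR of
  a grid spanning [-10, 10] dB (default 30 subjects x 100 environments);
* a 3-class classification set labeled drowsiness / normal / stress, where
  drowsiness means both rates below the normal range and stress both above
  (default 20+16+17 subjects x 100 environments);
* a generalization set of unseen subjects, 5 per state, carrying both the
  continuous and the class labels (default 15 x 100).

Splits are 64/16/20 train/validation/test with a fixed shuffle seed, and
stratified by class for the classification task.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from fractions import Fraction
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.signal

from .signal_model import (
    BasebandRecord,
    RadarConfig,
    VitalSignParameters,
    synthesize_baseband,
)

__all__ = [
    "NORMAL_FC_HZ",
    "NORMAL_FR_HZ",
    "ClassBands",
    "SubjectGrid",
    "SignalDataset",
    "snr_grid",
    "build_regression_dataset",
    "build_classification_dataset",
    "build_generalization_dataset",
    "split_dataset",
    "resample_and_segment",
    "derive_seed",
]

#: normal adult ranges: 60-100 bpm hearts would be 0.83-1.67 Hz, but subjects
#: are drawn from the wider generation range [0.83, 2] Hz used for the corpus;
#: respiration 10-20 breaths/min.
NORMAL_FC_HZ = (0.83, 2.0)
NORMAL_FR_HZ = (0.16, 0.33)

AC_RANGE_M = (2e-4, 5e-4)
AR_RANGE_M = (4e-3, 12e-3)
D0_RANGE_M = (0.6, 1.0)

STATES = ("drowsiness", "normal", "stress")


def derive_seed(seed: int, name: str) -> int:
    """Deterministically derive a per-stage 31-bit seed from (seed, name)."""
    import zlib

    return int(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass(frozen=True)
class ClassBands:
    """(Fc, Fr) sampling bands per physiological state.

    The out-of-range bands are physiologically plausible margins below /
    above the normal ranges (bradycardia-like and tachycardia-like rates).
    """

    normal_fc: Tuple[float, float] = NORMAL_FC_HZ
    normal_fr: Tuple[float, float] = NORMAL_FR_HZ
    drowsy_fc: Tuple[float, float] = (0.55, 0.83)
    drowsy_fr: Tuple[float, float] = (0.10, 0.16)
    stress_fc: Tuple[float, float] = (2.0, 2.5)
    stress_fr: Tuple[float, float] = (0.33, 0.50)

    def bands_for(self, state: str):
        return {
            "normal": (self.normal_fc, self.normal_fr),
            "drowsiness": (self.drowsy_fc, self.drowsy_fr),
            "stress": (self.stress_fc, self.stress_fr),
        }[state]


@dataclass
class SubjectGrid:
    """The per-subject ground-truth (Fc, Fr) pairs and their state labels."""

    pairs: List[Tuple[float, float]]
    class_labels: Optional[List[str]] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.class_labels is not None:
            if len(self.class_labels) != len(self.pairs):
                raise ValueError("class_labels length mismatch")
            bands = ClassBands()
            for (fc, fr), st in zip(self.pairs, self.class_labels):
                if st == "normal":
                    ok = NORMAL_FC_HZ[0] <= fc <= NORMAL_FC_HZ[1] and (
                        NORMAL_FR_HZ[0] <= fr <= NORMAL_FR_HZ[1]
                    )
                elif st == "drowsiness":
                    ok = fc < NORMAL_FC_HZ[0] and fr < NORMAL_FR_HZ[0]
                elif st == "stress":
                    ok = fc > NORMAL_FC_HZ[1] and fr > NORMAL_FR_HZ[1]
                else:
                    raise ValueError(f"unknown state {st!r}")
                if not ok:
                    raise ValueError(f"pair ({fc}, {fr}) violates {st} band rule")


@dataclass
class SignalDataset:
    """Ordered collection of baseband records with labels and split tags."""

    records: List[BasebandRecord]
    task: str  # "regression" | "classification"
    split_assignments: Optional[np.ndarray] = None  # "train"/"val"/"test" per record
    class_names: Tuple[str, ...] = STATES
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.records)

    def iq_array(self) -> np.ndarray:
        return np.stack([r.iq for r in self.records])

    def rate_labels(self) -> np.ndarray:
        """(n, 2) array of (fc_hz, fr_hz)."""
        return np.array([[r.fc_hz, r.fr_hz] for r in self.records])

    def state_indices(self) -> np.ndarray:
        """Integer class labels following ``class_names`` order."""
        lut = {s: i for i, s in enumerate(self.class_names)}
        return np.array([lut[r.state] for r in self.records], dtype=np.int64)

    def one_hot_labels(self) -> np.ndarray:
        idx = self.state_indices()
        out = np.zeros((len(idx), len(self.class_names)))
        out[np.arange(len(idx)), idx] = 1.0
        return out

    def indices_of(self, split: str) -> np.ndarray:
        if self.split_assignments is None:
            raise ValueError("dataset has no split assignments; call split_dataset")
        return np.flatnonzero(self.split_assignments == split)

    def subset(self, split: str) -> "SignalDataset":
        idx = self.indices_of(split)
        return SignalDataset(
            records=[self.records[i] for i in idx],
            task=self.task,
            class_names=self.class_names,
            meta={**self.meta, "subset": split},
        )

    def label_manifest(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.records):
            rows.append(
                {
                    "index": i,
                    "fc_hz": r.fc_hz,
                    "fr_hz": r.fr_hz,
                    "state": r.state,
                    "snr_db": r.snr_db,
                    "seed": r.seed,
                    "split": None
                    if self.split_assignments is None
                    else self.split_assignments[i],
                }
            )
        return pd.DataFrame(rows)

    # ---- HDF5 serialization -------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py

        iq = self.iq_array()
        with h5py.File(path, "w") as f:
            g = f.create_group("records")
            g.create_dataset("i", data=iq.real)
            g.create_dataset("q", data=iq.imag)
            lab = f.create_group("labels")
            lab.create_dataset("rates", data=self.rate_labels())
            states = [r.state if r.state is not None else "" for r in self.records]
            lab.create_dataset("state", data=np.array(states, dtype="S16"))
            lab.create_dataset("snr_db", data=np.array([r.snr_db for r in self.records]))
            seeds = np.array([-1 if r.seed is None else r.seed for r in self.records])
            lab.create_dataset("seed", data=seeds)
            if self.split_assignments is not None:
                lab.create_dataset(
                    "split", data=np.asarray(self.split_assignments, dtype="S8")
                )
            m = f.create_group("meta")
            cfg = self.records[0].config if self.records else RadarConfig()
            m.attrs["task"] = self.task
            m.attrs["class_names"] = json.dumps(list(self.class_names))
            m.attrs["config"] = json.dumps(asdict(cfg))
            m.attrs["meta"] = json.dumps(self.meta, default=str)

    @classmethod
    def from_hdf5(cls, path) -> "SignalDataset":
        import h5py

        with h5py.File(path, "r") as f:
            iq = f["records/i"][...] + 1j * f["records/q"][...]
            rates = f["labels/rates"][...]
            states = [s.decode() or None for s in f["labels/state"][...]]
            snrs = f["labels/snr_db"][...]
            seeds = f["labels/seed"][...]
            split = None
            if "split" in f["labels"]:
                split = np.array([s.decode() for s in f["labels/split"][...]])
            cfg = RadarConfig(**json.loads(f["meta"].attrs["config"]))
            task = f["meta"].attrs["task"]
            class_names = tuple(json.loads(f["meta"].attrs["class_names"]))
            meta = json.loads(f["meta"].attrs["meta"])
        records = [
            BasebandRecord(
                iq=iq[i],
                fc_hz=float(rates[i, 0]),
                fr_hz=float(rates[i, 1]),
                snr_db=float(snrs[i]),
                state=states[i],
                seed=None if seeds[i] < 0 else int(seeds[i]),
                config=cfg,
            )
            for i in range(len(iq))
        ]
        return cls(records=records, task=str(task), split_assignments=split,
                   class_names=class_names, meta=meta)


def snr_grid(n_levels: int = 100, lo_db: float = -10.0, hi_db: float = 10.0):
    """Equally spaced SNR levels in dB, inclusive of both endpoints."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if not lo_db < hi_db:
        raise ValueError("lo_db must be < hi_db")
    return np.linspace(lo_db, hi_db, n_levels)


def _draw_pairs(rng, n, fc_band, fr_band):
    fc = rng.uniform(*fc_band, size=n)
    fr = rng.uniform(*fr_band, size=n)
    return list(zip(fc.tolist(), fr.tolist()))


def _records_for_pairs(
    pairs, states, config, snrs, seed, randomize_phases=True
) -> List[BasebandRecord]:
    records = []
    for i, ((fc, fr), st) in enumerate(zip(pairs, states)):
        sub_rng = np.random.default_rng(derive_seed(seed, f"subject-{i}"))
        ac = sub_rng.uniform(*AC_RANGE_M)
        ar = sub_rng.uniform(*AR_RANGE_M)
        for j, snr in enumerate(snrs):
            rec_seed = derive_seed(seed, f"record-{i}-{j}")
            rng = np.random.default_rng(rec_seed)
            d0 = rng.uniform(*D0_RANGE_M)
            phases = rng.uniform(0, 2 * np.pi, size=2) if randomize_phases else (0, 0)
            params = VitalSignParameters(
                fc_hz=fc, fr_hz=fr, ac_m=ac, ar_m=ar,
                phase_c_rad=float(phases[0]), phase_r_rad=float(phases[1]),
            )
            records.append(
                synthesize_baseband(
                    params,
                    replace(config, d0_m=float(d0)),
                    snr_db=float(snr),
                    rng=rng,
                    state=st,
                    seed=rec_seed,
                )
            )
    return records


def build_regression_dataset(
    n_subjects: int = 30,
    n_envs: int = 100,
    config: RadarConfig = RadarConfig(),
    seed: int = 0,
) -> SignalDataset:
    """Normal-state corpus labeled with (Fc, Fr); n_subjects x n_envs records."""
    rng = np.random.default_rng(derive_seed(seed, "regression-subjects"))
    pairs = _draw_pairs(rng, n_subjects, NORMAL_FC_HZ, NORMAL_FR_HZ)
    snrs = snr_grid(n_envs)
    records = _records_for_pairs(pairs, ["normal"] * len(pairs), config, snrs, seed)
    return SignalDataset(
        records=records,
        task="regression",
        meta={"pairs": pairs, "n_envs": n_envs, "seed": seed},
    )


def _classification_pairs(rng, n_normal, n_drowsy, n_stress, bands: ClassBands):
    pairs, states = [], []
    for n, state in ((n_normal, "normal"), (n_drowsy, "drowsiness"), (n_stress, "stress")):
        fc_band, fr_band = bands.bands_for(state)
        pairs += _draw_pairs(rng, n, fc_band, fr_band)
        states += [state] * n
    return pairs, states


def build_classification_dataset(
    n_normal: int = 20,
    n_drowsy: int = 16,
    n_stress: int = 17,
    n_envs: int = 100,
    config: RadarConfig = RadarConfig(),
    seed: int = 0,
    bands: ClassBands = ClassBands(),
) -> SignalDataset:
    """Three-state corpus with one-hot class labels; (20+16+17) x n_envs records."""
    rng = np.random.default_rng(derive_seed(seed, "classification-subjects"))
    pairs, states = _classification_pairs(rng, n_normal, n_drowsy, n_stress, bands)
    snrs = snr_grid(n_envs)
    records = _records_for_pairs(pairs, states, config, snrs, seed)
    return SignalDataset(
        records=records,
        task="classification",
        meta={"pairs": pairs, "states": states, "n_envs": n_envs, "seed": seed},
    )


def build_generalization_dataset(
    n_per_state: int = 5,
    n_envs: int = 100,
    config: RadarConfig = RadarConfig(),
    seed: int = 0,
    bands: ClassBands = ClassBands(),
    exclude_pairs: Sequence[Tuple[float, float]] = (),
) -> SignalDataset:
    """Unseen subjects, n_per_state per physiological state, with both labels.

    Pairs colliding exactly with ``exclude_pairs`` (e.g. the training
    subjects) are rejected and redrawn.
    """
    rng = np.random.default_rng(derive_seed(seed, "generalization-subjects"))
    excluded = set(map(tuple, exclude_pairs))
    pairs, states = [], []
    for state in STATES:
        fc_band, fr_band = bands.bands_for(state)
        drawn = 0
        while drawn < n_per_state:
            (pair,) = _draw_pairs(rng, 1, fc_band, fr_band)
            if pair in excluded:
                continue
            pairs.append(pair)
            states.append(state)
            excluded.add(pair)
            drawn += 1
    snrs = snr_grid(n_envs)
    records = _records_for_pairs(pairs, states, config, snrs, seed)
    return SignalDataset(
        records=records,
        task="regression",
        meta={"pairs": pairs, "states": states, "n_envs": n_envs, "seed": seed,
              "generalization": True},
    )


def _largest_remainder_counts(n: int, fractions) -> np.ndarray:
    exact = np.asarray(fractions) * n
    counts = np.floor(exact).astype(int)
    rem = exact - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return counts


def split_dataset(
    ds: SignalDataset,
    fractions=(0.64, 0.16, 0.20),
    seed: int = 4,
) -> SignalDataset:
    """Assign train/val/test tags by seeded shuffle (stratified for classification).

    Returns the same dataset object with ``split_assignments`` populated.
    """
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(ds)
    assignments = np.empty(n, dtype=object)
    rng = np.random.default_rng(seed)
    names = ("train", "val", "test")

    def assign(indices):
        indices = np.asarray(indices)
        perm = rng.permutation(len(indices))
        counts = _largest_remainder_counts(len(indices), fractions)
        start = 0
        for name, cnt in zip(names, counts):
            assignments[indices[perm[start : start + cnt]]] = name
            start += cnt

    if ds.task == "classification":
        labels = ds.state_indices()
        for cls in np.unique(labels):
            assign(np.flatnonzero(labels == cls))
    else:
        assign(np.arange(n))
    ds.split_assignments = np.array([str(a) for a in assignments])
    return ds


def resample_and_segment(
    iq: np.ndarray,
    fs_in: float,
    fs_out: float = 100.0,
    window: int = 5001,
) -> List[np.ndarray]:
    """Anti-aliased rational resampling followed by non-overlapping windowing.

    Externally recorded I/Q streams (e.g. 2000 Hz acquisitions) are brought to
    the working rate and cut into consecutive segments of exactly ``window``
    samples; the trailing remainder is dropped. Returns a (possibly empty)
    list of complex arrays.
    """
    if not (fs_in >= fs_out > 0):
        raise ValueError("need fs_in >= fs_out > 0")
    iq = np.asarray(iq)
    if fs_in == fs_out:
        resampled = iq
    else:
        frac = Fraction(fs_out / fs_in).limit_denominator(10**6)
        up, down = frac.numerator, frac.denominator
        resampled = scipy.signal.resample_poly(iq, up, down)
    n_windows = len(resampled) // window
    return [resampled[k * window : (k + 1) * window] for k in range(n_windows)]
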