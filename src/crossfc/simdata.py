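"""Synthetic crossover rsfMRI cohorts with known ground truth.

Generates 4D BOLD sessions, tissue masks, motion traces and a design table
for a two-treatment (placebo / verum), two-period (RS0 pre-dose / RS1
post-dose) crossover cohort.  Connectivity structure is planted explicitly:

* **hub communities** — sets of gray-matter voxels sharing a common
  band-limited latent signal, so they form a dense correlation clique and
  acquire high functional connectivity density;
* **seed–target coupling** — the seed region carries a latent ``u`` and the
  target region carries ``r*u + sqrt(1-r^2)*v`` with ``v`` independent, so
  the expected seed–target correlation of the latent parts is exactly ``r``
  (negative ``r`` plants anticorrelation);
* **time-by-drug interaction** — the planted coupling changes from RS0 to
  RS1 under verum by ``interaction_delta`` and stays flat under placebo;
* **nuisance structure** — white-matter and CSF masks carry their own
  common signals, and motion spikes add both a transient translation in the
  motion file and a global intensity offset in the BOLD volume.

All latent signals are unit-variance Gaussian processes band-limited to the
infra-slow band (0.01–0.1 Hz by default) so that they survive the band-pass
stage of preprocessing and recovery tests probe the analysis, not the
generator.  Everything is driven by :class:`numpy.random.Generator` streams
spawned deterministically from ``SimConfig.rng_seed``, so an identical
configuration reproduces the cohort bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

DRUGS = ("placebo", "verum")
SESSIONS = ("RS0", "RS1")
SEQUENCES = ("verum-first", "placebo-first")

__all__ = [
    "Box",
    "SimConfig",
    "MaskSet",
    "BoldSeries",
    "MotionTrace",
    "GroundTruth",
    "SessionRecord",
    "Cohort",
    "default_config",
    "build_masks",
    "generate_session",
    "generate_cohort",
    "analyzed_bad_indices",
    "bandlimited_noise",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned voxel box, the region primitive of the simulator."""

    origin: tuple[int, int, int]
    shape: tuple[int, int, int]

    def mask(self, grid_shape: Sequence[int]) -> np.ndarray:
        self.validate(grid_shape)
        m = np.zeros(tuple(grid_shape), dtype=bool)
        sl = tuple(slice(o, o + s) for o, s in zip(self.origin, self.shape))
        m[sl] = True
        return m

    def validate(self, grid_shape: Sequence[int]) -> None:
        for o, s, g in zip(self.origin, self.shape, grid_shape):
            if o < 0 or s < 1 or o + s > g:
                raise ValueError(
                    f"region box {self.origin}+{self.shape} does not fit grid {tuple(grid_shape)}"
                )

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class BoldSeries:
    """One session's 4D BOLD signal on a regular grid."""

    data: np.ndarray          # (x, y, z, t)
    affine: np.ndarray        # 4x4 grid-to-mm
    tr_s: float

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if self.data.shape[3] < 1:
            raise ValueError("BOLD series needs at least one volume")
        if self.tr_s <= 0:
            raise ValueError("repetition time must be positive")
        if abs(np.linalg.det(np.asarray(self.affine))) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class MotionTrace:
    """Per-volume rigid-body parameters: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray        # (t, 6)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must have shape (n_volumes, 6)")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    def trimmed(self, n: int) -> "MotionTrace":
        return MotionTrace(self.params[n:].copy())


@dataclass
class MaskSet:
    """Binary tissue/region masks sharing the BOLD grid."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    seed: np.ndarray
    target: np.ndarray
    hubs: tuple[np.ndarray, ...]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = self.gm.shape
        for name in ("wm", "csf", "seed", "target"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"mask '{name}' not on the BOLD grid")
        if (self.seed & ~self.gm).any():
            raise ValueError("seed mask must lie inside gray matter")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.gm.shape


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic crossover cohort.

    Defaults reproduce the acquisition of the emulated trial: TR 2 s,
    355 volumes per session (5 of which downstream analysis discards),
    3 mm isotropic voxels, 35 subjects split 18/17 between the two
    treatment sequences, ages uniform on [31, 59].  The spatial grid is a
    compact 12^3 block rather than a whole-brain field of view; region
    geometry is a caricature chosen for testability.
    """

    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.0
    n_volumes: int = 355
    n_subjects: int = 35
    # regions
    hub_spec: tuple[tuple[Box, float], ...] = (
        (Box((7, 7, 7), (3, 3, 3)), 2.0),
    )
    seed_region: Box = Box((5, 1, 1), (2, 2, 2))
    target_region: Box = Box((9, 2, 8), (2, 2, 2))
    # planted couplings
    coupling_r: float = -0.5
    interaction_delta: float = -0.25
    subject_coupling_sd: float = 0.08
    signal_amplitude: float = 1.5
    # nuisance structure
    wm_amplitude: float = 1.0
    csf_amplitude: float = 1.0
    spike_rate: float = 0.02
    spike_translation_mm: float = 1.5
    spike_intensity: float = 4.0
    # noise & band
    noise_sd: float = 1.0
    band_hz: tuple[float, float] = (0.01, 0.1)
    age_range: tuple[float, float] = (31.0, 59.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(g < 4 for g in self.grid_shape):
            raise ValueError("each grid axis must be >= 4")
        if not (-1.0 < self.coupling_r < 1.0):
            raise ValueError("|coupling_r| must be < 1")
        if self.n_volumes < 1 or self.n_subjects < 0:
            raise ValueError("n_volumes >= 1 and n_subjects >= 0 required")
        if self.noise_sd < 0 or self.tr_s <= 0 or self.voxel_size_mm <= 0:
            raise ValueError("noise_sd >= 0 and positive tr/voxel size required")
        amps = [a for _, a in self.hub_spec] + [
            self.signal_amplitude, self.wm_amplitude, self.csf_amplitude,
            self.spike_intensity, self.noise_sd,
        ]
        if not np.all(np.isfinite(amps)):
            raise ValueError("all amplitudes must be finite")
        f_lo, f_hi = self.band_hz
        if not (0 < f_lo < f_hi < 0.5 / self.tr_s):
            raise ValueError("band must satisfy 0 < f_lo < f_hi < Nyquist")

    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def cell_coupling(self, drug: str, session: str) -> float:
        """Planted latent seed–target correlation for one design cell.

        Placebo is flat across sessions; verum shifts by ``interaction_delta``
        at RS1, so the difference-of-differences over the 2x2 equals
        ``interaction_delta`` exactly.
        """
        r = self.coupling_r
        if drug == "verum" and session == "RS1":
            r += self.interaction_delta
        return float(np.clip(r, -0.99, 0.99))


@dataclass
class GroundTruth:
    """What was planted, for recovery tests."""

    hub_mask: np.ndarray
    seed_mask: np.ndarray
    target_mask: np.ndarray
    expected_r: dict            # (drug, session) -> attenuated seed-target r
    bad_volumes: dict           # (subject, drug, session) -> original volume indices
    ages: dict                  # subject -> years
    sequences: dict             # subject -> sequence label
    coupling_offsets: dict      # subject -> latent coupling jitter


@dataclass
class SessionRecord:
    subject: str
    sequence: str
    drug: str
    session: str
    age: float
    bold: BoldSeries | None = None
    motion: MotionTrace | None = None
    bold_path: str | None = None
    motion_path: str | None = None


@dataclass
class Cohort:
    sessions: list
    masks: MaskSet
    design: "object"            # pandas.DataFrame; imported lazily in io
    truth: GroundTruth
    config: SimConfig


def default_config(**overrides) -> SimConfig:
    return SimConfig(**overrides)


def bandlimited_noise(
    rng: np.random.Generator,
    n: int,
    tr_s: float,
    band_hz: tuple[float, float],
    size: int | tuple = 1,
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band_hz``.

    White noise is padded, passed through a zero-phase 4th-order Butterworth
    band-pass, cropped, and re-standardized, giving stationary series whose
    power is concentrated (>90%) inside the band.
    """
    fs = 1.0 / tr_s
    pad = max(64, n // 2)
    shape = (size, n + 2 * pad) if np.isscalar(size) else tuple(size) + (n + 2 * pad,)
    white = rng.standard_normal(shape)
    sos = signal.butter(4, band_hz, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, white, axis=-1)
    filt = filt[..., pad:pad + n]
    sd = filt.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    out = (filt - filt.mean(axis=-1, keepdims=True)) / sd
    return out[0] if size == 1 else out


def build_masks(config: SimConfig) -> MaskSet:
    """Partition the grid into WM / CSF slabs and a gray-matter block.

    WM occupies the first sixth of the x axis, CSF the next sixth, gray
    matter the remainder.  Seed, target and hub boxes must sit inside gray
    matter; a grid too small to hold them raises ``ValueError``.
    """
    gx, gy, gz = config.grid_shape
    wm_end = max(1, gx // 6)
    csf_end = max(wm_end + 1, gx // 3)
    if csf_end >= gx - 1:
        raise ValueError(f"grid x-extent {gx} too small for tissue layout")
    idx = np.arange(gx)
    wm = np.zeros(config.grid_shape, dtype=bool)
    csf = np.zeros(config.grid_shape, dtype=bool)
    gm = np.zeros(config.grid_shape, dtype=bool)
    wm[idx < wm_end] = True
    csf[(idx >= wm_end) & (idx < csf_end)] = True
    gm[idx >= csf_end] = True

    seed = config.seed_region.mask(config.grid_shape)
    target = config.target_region.mask(config.grid_shape)
    hubs = tuple(box.mask(config.grid_shape) for box, _ in config.hub_spec)
    for name, m in (("seed", seed), ("target", target)) + tuple(
        (f"hub{i}", h) for i, h in enumerate(hubs)
    ):
        if not m[gm].sum() == m.sum():
            raise ValueError(f"region '{name}' extends outside gray matter; grid too small or origin misplaced")
    if (seed & target).any():
        raise ValueError("seed and target regions overlap")
    return MaskSet(gm=gm, wm=wm, csf=csf, seed=seed, target=target,
                   hubs=hubs, affine=config.affine())


def _expected_observed_r(config: SimConfig, latent_r: float) -> float:
    """Expected sample correlation of seed-mean vs target-mean time courses.

    Averaging m voxels leaves signal a*u intact but shrinks the noise to
    sd/sqrt(m); the latent correlation is attenuated by the product of the
    two regions' signal fractions.
    """
    a2 = config.signal_amplitude ** 2
    m_seed = config.seed_region.n_voxels
    m_tgt = config.target_region.n_voxels
    g_seed = a2 / (a2 + config.noise_sd ** 2 / m_seed)
    g_tgt = a2 / (a2 + config.noise_sd ** 2 / m_tgt)
    return latent_r * np.sqrt(g_seed * g_tgt)


def _session_rng(config: SimConfig, subject_index: int, drug: str, session: str) -> np.random.Generator:
    return np.random.default_rng(
        [config.rng_seed & 0x7FFFFFFF, subject_index,
         DRUGS.index(drug), SESSIONS.index(session)]
    )


def generate_session(
    config: SimConfig,
    subject_id: str | int,
    drug: str,
    session: str,
    rng: np.random.Generator | None = None,
    coupling_offset: float = 0.0,
) -> tuple[BoldSeries, MotionTrace, GroundTruth]:
    """Generate one session's BOLD + motion + ground truth.

    ``rng`` defaults to a stream derived deterministically from the config
    seed and the (subject, drug, session) coordinates, so cohorts are
    reproducible regardless of generation order.
    """
    if drug not in DRUGS:
        raise ValueError(f"drug must be one of {DRUGS}")
    if session not in SESSIONS:
        raise ValueError(f"session must be one of {SESSIONS}")
    masks = build_masks(config)
    if rng is None:
        sub_index = subject_id if isinstance(subject_id, int) else abs(hash(subject_id)) % (2 ** 31)
        rng = _session_rng(config, sub_index, drug, session)

    T = config.n_volumes
    r_cell = float(np.clip(config.cell_coupling(drug, session) + coupling_offset, -0.99, 0.99))

    n_lat = len(config.hub_spec) + 4        # hubs + seed u + target v + wm + csf
    lat = bandlimited_noise(rng, T, config.tr_s, config.band_hz, size=n_lat)
    hub_lat = lat[: len(config.hub_spec)]
    u_seed, v_tgt, u_wm, u_csf = lat[len(config.hub_spec):]

    data = rng.standard_normal(config.grid_shape + (T,)) * config.noise_sd
    a = config.signal_amplitude
    for (box, amp), u in zip(config.hub_spec, hub_lat):
        m = box.mask(config.grid_shape)
        # heterogeneous hub strength: voxels participate in the community
        # with varying weight (weak members fall below the edge threshold
        # against other weak members even after band-pass denoising), so
        # edge counts vary across voxels and sessions instead of forming
        # a deterministic clique
        weights = amp * rng.uniform(0.25, 1.75, size=int(m.sum()))
        data[m] += weights[:, None] * u
    data[masks.seed] += a * u_seed
    tgt_sig = r_cell * u_seed + np.sqrt(1.0 - r_cell ** 2) * v_tgt
    data[masks.target] += a * tgt_sig
    data[masks.wm] += config.wm_amplitude * u_wm
    data[masks.csf] += config.csf_amplitude * u_csf

    # realistic-but-small motion background
    motion = np.empty((T, 6))
    motion[:, :3] = rng.normal(0.0, 0.01, (T, 3))
    motion[:, 3:] = rng.normal(0.0, 1e-4, (T, 3))
    # transient, isolated artifacts: never two adjacent spike volumes
    candidates = np.flatnonzero(rng.random(T) < config.spike_rate)
    spikes = []
    for t in candidates:
        if not spikes or t - spikes[-1] > 1:
            spikes.append(int(t))
    spikes = np.asarray(spikes, dtype=int)
    for t in spikes:
        motion[t, 0] += config.spike_translation_mm
        data[..., t] += config.spike_intensity * max(config.noise_sd, 1.0)

    bold = BoldSeries(data=data, affine=config.affine(), tr_s=config.tr_s)
    hub_union = np.zeros(config.grid_shape, dtype=bool)
    for h in masks.hubs:
        hub_union |= h
    truth = GroundTruth(
        hub_mask=hub_union,
        seed_mask=masks.seed,
        target_mask=masks.target,
        expected_r={(drug, session): _expected_observed_r(config, r_cell)},
        bad_volumes={(str(subject_id), drug, session): spikes},
        ages={}, sequences={}, coupling_offsets={},
    )
    return bold, MotionTrace(motion), truth


def analyzed_bad_indices(original_indices: Iterable[int], n_discard: int) -> np.ndarray:
    """Shift planted bad-volume indices into post-discard coordinates."""
    idx = np.asarray(sorted(original_indices), dtype=int)
    return idx[idx >= n_discard] - n_discard


def _sequence_assignment(n_subjects: int) -> list[str]:
    """Near-even split; with 35 subjects this yields 18 verum-first, 17 placebo-first."""
    n_verum_first = (n_subjects + 1) // 2
    return ["verum-first"] * n_verum_first + ["placebo-first"] * (n_subjects - n_verum_first)


def generate_cohort(config: SimConfig, out_dir=None) -> Cohort:
    """Generate the full 2-drug x 2-session cohort.

    With ``out_dir`` set, BOLD volumes, masks and motion files are written
    (NIfTI-1 / SPM rp text) and a design table CSV is produced; otherwise
    everything stays in memory.  ``n_subjects == 0`` yields a valid empty
    cohort.
    """
    import pandas as pd

    masks = build_masks(config)
    cohort_rng = np.random.default_rng([config.rng_seed & 0x7FFFFFFF, 4071])
    ages = cohort_rng.uniform(*config.age_range, size=config.n_subjects)
    offsets = cohort_rng.normal(0.0, config.subject_coupling_sd, size=config.n_subjects)
    sequences = _sequence_assignment(config.n_subjects)

    sessions: list[SessionRecord] = []
    truth = GroundTruth(
        hub_mask=np.zeros(config.grid_shape, dtype=bool),
        seed_mask=masks.seed, target_mask=masks.target,
        expected_r={}, bad_volumes={}, ages={}, sequences={}, coupling_offsets={},
    )
    for h in masks.hubs:
        truth.hub_mask |= h
    for drug in DRUGS:
        for sess in SESSIONS:
            truth.expected_r[(drug, sess)] = _expected_observed_r(
                config, config.cell_coupling(drug, sess))

    rows = []
    if out_dir is not None:
        from . import io as cio
        out_dir = cio.ensure_dir(out_dir)
        cio.write_masks(out_dir, masks)

    for i in range(config.n_subjects):
        sid = f"sub-{i + 1:03d}"
        truth.ages[sid] = float(ages[i])
        truth.sequences[sid] = sequences[i]
        truth.coupling_offsets[sid] = float(offsets[i])
        for drug in DRUGS:
            for sess in SESSIONS:
                rng = _session_rng(config, i, drug, sess)
                bold, motion, st = generate_session(
                    config, i, drug, sess, rng=rng, coupling_offset=offsets[i])
                truth.bad_volumes[(sid, drug, sess)] = st.bad_volumes[(str(i), drug, sess)]
                rec = SessionRecord(subject=sid, sequence=sequences[i], drug=drug,
                                    session=sess, age=float(ages[i]),
                                    bold=bold, motion=motion)
                if out_dir is not None:
                    from . import io as cio
                    bpath = out_dir / f"{sid}_{drug}_{sess}_bold.nii.gz"
                    mpath = out_dir / f"rp_{sid}_{drug}_{sess}.txt"
                    cio.write_bold(bpath, bold)
                    cio.write_motion(mpath, motion)
                    rec.bold_path, rec.motion_path = str(bpath), str(mpath)
                    rec.bold, rec.motion = None, None
                sessions.append(rec)
                rows.append({
                    "subject": sid, "sequence": sequences[i], "drug": drug,
                    "session": sess, "age": float(ages[i]),
                    "bold_path": rec.bold_path or "", "motion_path": rec.motion_path or "",
                })

    design = pd.DataFrame(rows, columns=["subject", "sequence", "drug", "session",
                                         "age", "bold_path", "motion_path"])
    if out_dir is not None:
        design.to_csv(out_dir / "design.csv", index=False)
    return Cohort(sessions=sessions, masks=masks, design=design,
                  truth=truth, config=config)
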