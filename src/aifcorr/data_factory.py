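"""Assembly of simulated curve-set datasets.

One *curve set* is the unit record used for network training and
evaluation: a true AIF, the corresponding saturated-and-biased AIF after
the dictionary round trip, up to eleven tissue curves (after the same
round trip), and all generating parameters.  One bias draw is shared by
the AIF and tissue forward conversions of a set, mirroring a single scan.

This module also provides a synthetic stand-in for in vivo pixel-wise
myocardial curves: a clustered pixel generator plus K-means reduction to
a few representative tissue curves, and the interpolation/alignment
preprocessing used for externally measured curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .grid import ConcentrationCurve, TimeGrid
from .aif_population import AIFParams, sample_aif_params, evaluate_aif, AIF_PARAM_RANGES
from .tissue_kinetics import PKParams, VeRange, ladder_pk_set, tissue_curve
from .sequence_signal import (
    BiasFactors,
    NOMINAL_BIAS,
    SequenceParams,
    SignalDictionary,
    build_dictionary,
    simulate_signal,
    add_noise,
    sample_bias,
)

__all__ = [
    "CurveSet",
    "DatasetSpec",
    "Dataset",
    "make_curve_set",
    "make_dataset",
    "simulate_pixel_curves",
    "cluster_tissue_curves",
    "preprocess_curve",
]


@dataclass
class CurveSet:
    """One training/test record; all curves share one :class:`TimeGrid`."""

    true_aif: ConcentrationCurve
    saturated_aif: ConcentrationCurve
    tissue_curves: list[ConcentrationCurve]
    pk_params: list[PKParams]
    bias: BiasFactors
    aif_params: AIFParams

    def __post_init__(self) -> None:
        if len(self.tissue_curves) != len(self.pk_params):
            raise ValueError("one PKParams per tissue curve required")
        if len(self.tissue_curves) > 11:
            raise ValueError("at most 11 tissue curves per set")

    @property
    def grid(self) -> TimeGrid:
        return self.true_aif.grid


@dataclass(frozen=True)
class DatasetSpec:
    """Recipe for one seeded train/validation/test dataset."""

    n_train: int = 8000
    n_val: int = 1000
    n_test: int = 1000
    n_tissue: int = 10
    tissue_sampler: str = "ladder"  # or "random" (curves sorted by peak)
    bias_mode: str = "symmetric"
    bias_magnitude: float = 0.1
    val_bias_magnitude: float | None = None
    noisy: bool = True
    noise_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_val, self.n_test) <= 0:
            raise ValueError("split sizes must be positive")
        if not 0 <= self.n_tissue <= 11:
            raise ValueError("n_tissue must be in 0..11")
        if self.tissue_sampler not in ("ladder", "random"):
            raise ValueError(f"unknown tissue sampler {self.tissue_sampler!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Dataset:
    """Array-form dataset split, ready for batching.

    ``true_aif``/``sat_aif`` have shape (n, T); ``tissue`` (n, N, T);
    ``pk`` (n, N, 4) ordered (ktrans, kep, vp, delta_t); ``bias`` (n, 3)
    ordered (fa_scale, t2s_scale, residual_mz).
    """

    grid: TimeGrid
    true_aif: np.ndarray
    sat_aif: np.ndarray
    tissue: np.ndarray
    pk: np.ndarray
    bias: np.ndarray

    @property
    def n_sets(self) -> int:
        return self.true_aif.shape[0]

    @property
    def n_tissue(self) -> int:
        return self.tissue.shape[1]

    def curve_set(self, i: int) -> tuple[ConcentrationCurve, ConcentrationCurve, list[ConcentrationCurve], np.ndarray]:
        """Convenience view of record ``i`` as curves (true, saturated, tissue, pk)."""
        g = self.grid
        tissues = [ConcentrationCurve(g, self.tissue[i, j]) for j in range(self.n_tissue)]
        return (
            ConcentrationCurve(g, self.true_aif[i]),
            ConcentrationCurve(g, self.sat_aif[i]),
            tissues,
            self.pk[i],
        )

    def save(self, h5group) -> None:
        h5group.create_dataset("true_aif", data=self.true_aif)
        h5group.create_dataset("sat_aif", data=self.sat_aif)
        h5group.create_dataset("tissue", data=self.tissue)
        h5group.create_dataset("pk", data=self.pk)
        h5group.create_dataset("bias", data=self.bias)
        h5group.attrs["n_points"] = self.grid.n_points
        h5group.attrs["dt"] = self.grid.dt

    @classmethod
    def load(cls, h5group) -> "Dataset":
        grid = TimeGrid(int(h5group.attrs["n_points"]), float(h5group.attrs["dt"]))
        return cls(
            grid=grid,
            true_aif=h5group["true_aif"][:],
            sat_aif=h5group["sat_aif"][:],
            tissue=h5group["tissue"][:],
            pk=h5group["pk"][:],
            bias=h5group["bias"][:],
        )


def make_curve_set(
    rng: np.random.Generator,
    spec: DatasetSpec,
    dictionary: SignalDictionary,
    grid: TimeGrid | None = None,
    bias: BiasFactors | None = None,
    bias_magnitude: float | None = None,
) -> CurveSet:
    """Generate one curve set through the full forward pipeline.

    True AIF -> tissue curves (the fixed-ktrans ladder, or random-sampler
    parameters with curves sorted by ascending peak) -> biased forward
    signal conversion (one bias draw shared by all curves of the set) ->
    optional SI-domain noise -> nominal dictionary inversion of every
    curve.
    """
    grid = grid or TimeGrid()
    seq = dictionary.seq
    aif_params = sample_aif_params(rng)
    true_aif = evaluate_aif(aif_params, grid)
    n_tissue = spec.n_tissue
    if not n_tissue:
        pk_list = []
        tissue_gd = np.empty((0, grid.n_points))
    elif spec.tissue_sampler == "ladder":
        pk_list = ladder_pk_set(n_tissue, rng=rng)
        tissue_gd = np.array([tissue_curve(true_aif, p).values for p in pk_list])
    else:
        from .tissue_kinetics import sample_pk_params

        pk_list = [sample_pk_params(rng) for _ in range(n_tissue)]
        tissue_gd = np.array([tissue_curve(true_aif, p).values for p in pk_list])
        order = np.argsort(tissue_gd.max(axis=1))
        pk_list = [pk_list[i] for i in order]
        tissue_gd = tissue_gd[order]

    if bias is None:
        magnitude = bias_magnitude if bias_magnitude is not None else spec.bias_magnitude
        bias = sample_bias(rng, spec.bias_mode, magnitude)

    aif_si = simulate_signal(true_aif.values, seq, bias)
    # noise level is set by the tissue curves even when they are not
    # network inputs, so an AIF-only set still carries realistic noise
    noise_ref_gd = tissue_gd if n_tissue else np.array(
        [tissue_curve(true_aif, p).values for p in ladder_pk_set(1, rng=rng)]
    )
    tissue_si = simulate_signal(noise_ref_gd, seq, bias) if noise_ref_gd.size else noise_ref_gd
    if spec.noisy:
        aif_si, tissue_si = add_noise(aif_si, tissue_si, rng, spec.noise_fraction)

    sat_aif = ConcentrationCurve(grid, dictionary.to_concentration(aif_si))
    tissues = [
        ConcentrationCurve(grid, dictionary.to_concentration(tissue_si[j]))
        for j in range(n_tissue)
    ]
    return CurveSet(
        true_aif=true_aif,
        saturated_aif=sat_aif,
        tissue_curves=tissues,
        pk_params=pk_list,
        bias=bias,
        aif_params=aif_params,
    )


def _generate_split(
    seed_seq: np.random.SeedSequence,
    n_sets: int,
    spec: DatasetSpec,
    dictionary: SignalDictionary,
    grid: TimeGrid,
    bias_magnitude: float,
) -> Dataset:
    rng = np.random.default_rng(seed_seq)
    n_t = spec.n_tissue
    true_aif = np.empty((n_sets, grid.n_points))
    sat_aif = np.empty((n_sets, grid.n_points))
    tissue = np.empty((n_sets, n_t, grid.n_points))
    pk = np.empty((n_sets, n_t, 4))
    bias_arr = np.empty((n_sets, 3))
    for i in range(n_sets):
        cs = make_curve_set(rng, spec, dictionary, grid, bias_magnitude=bias_magnitude)
        true_aif[i] = cs.true_aif.values
        sat_aif[i] = cs.saturated_aif.values
        for j in range(n_t):
            tissue[i, j] = cs.tissue_curves[j].values
            pk[i, j] = cs.pk_params[j].to_array()
        bias_arr[i] = (cs.bias.fa_scale, cs.bias.t2s_scale, cs.bias.residual_mz)
    return Dataset(grid=grid, true_aif=true_aif, sat_aif=sat_aif, tissue=tissue, pk=pk, bias=bias_arr)


def make_dataset(
    spec: DatasetSpec,
    dictionary: SignalDictionary | None = None,
    grid: TimeGrid | None = None,
) -> dict[str, Dataset]:
    """Generate the train/val/test splits from disjoint seeded substreams.

    The validation split may use a wider bias range than training
    (``val_bias_magnitude``), the configuration used when adapting the
    training distribution to more diverse test data.
    """
    grid = grid or TimeGrid()
    dictionary = dictionary or build_dictionary()
    root = np.random.SeedSequence(spec.seed)
    train_ss, val_ss, test_ss = root.spawn(3)
    val_mag = spec.val_bias_magnitude if spec.val_bias_magnitude is not None else spec.bias_magnitude
    return {
        "train": _generate_split(train_ss, spec.n_train, spec, dictionary, grid, spec.bias_magnitude),
        "val": _generate_split(val_ss, spec.n_val, spec, dictionary, grid, val_mag),
        "test": _generate_split(test_ss, spec.n_test, spec, dictionary, grid, spec.bias_magnitude),
    }


def save_dataset(splits: dict[str, Dataset], spec: DatasetSpec, path) -> None:
    """Persist splits plus a manifest of the generating spec."""
    import h5py

    with h5py.File(path, "w") as f:
        for name, ds in splits.items():
            ds.save(f.create_group(name))
        f.attrs["spec"] = json.dumps(spec.to_dict())


def load_dataset(path) -> tuple[dict[str, Dataset], DatasetSpec]:
    import h5py

    with h5py.File(path, "r") as f:
        splits = {name: Dataset.load(f[name]) for name in f}
        spec = DatasetSpec(**json.loads(f.attrs["spec"]))
    return splits, spec


def simulate_pixel_curves(
    rng: np.random.Generator,
    aif: ConcentrationCurve,
    n_pixels: int = 500,
    n_clusters: int = 4,
    jitter: float = 0.1,
    noise_fraction: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic pixel-wise myocardial curves (stand-in for in vivo data).

    Draws ``n_clusters`` PK parameter sets, assigns pixels round-robin to
    clusters, jitters each pixel's parameters by +/- ``jitter`` relative,
    generates tissue curves and adds Gaussian noise at ``noise_fraction``
    of the mean curve peak.  Returns (curves, labels) with curves of
    shape (n_pixels, T).
    """
    if n_clusters > n_pixels:
        raise ValueError("need at least one pixel per cluster")
    from .tissue_kinetics import sample_pk_params

    base = [sample_pk_params(rng).to_array() for _ in range(n_clusters)]
    labels = np.arange(n_pixels) % n_clusters
    curves = np.empty((n_pixels, aif.grid.n_points))
    for i in range(n_pixels):
        p = base[labels[i]] * (1.0 + rng.uniform(-jitter, jitter, size=4))
        curves[i] = tissue_curve(aif, PKParams.from_array(np.clip(p, 0, None))).values
    if noise_fraction > 0:
        sigma = noise_fraction * float(curves.max(axis=1).mean())
        curves = curves + rng.normal(0.0, sigma, size=curves.shape)
    return curves, labels


def cluster_tissue_curves(pixel_curves: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """K-means reduction of pixel curves to ``k`` mean curves.

    Euclidean distance on the full time vector, 10 restarts, fixed seed;
    centres are returned sorted by descending peak value so the output
    ordering is deterministic.
    """
    pixel_curves = np.atleast_2d(np.asarray(pixel_curves, dtype=float))
    if not 1 <= k <= pixel_curves.shape[0]:
        raise ValueError("k must be between 1 and the number of pixel curves")
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(pixel_curves)
    centers = km.cluster_centers_
    order = np.argsort(-centers.max(axis=1))
    return centers[order]


def preprocess_curve(
    times_s: np.ndarray,
    values: np.ndarray,
    grid: TimeGrid | None = None,
    arrival_index: int = 10,
    arrival_threshold: float = 0.1,
) -> ConcentrationCurve:
    """Interpolate and align a measured curve onto the canonical grid.

    ``times_s`` are sample times in seconds (strictly increasing).  The
    curve is linearly interpolated to the 0.5 s grid, then shifted so
    that bolus arrival -- the first sample exceeding ``arrival_threshold``
    of the curve peak -- lands at ``arrival_index``.  Regions outside the
    measured span are zero-filled, making the operation shift-invariant
    with respect to the input timestamps.
    """
    times_s = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if times_s.ndim != 1 or times_s.size < 2:
        raise ValueError("need at least two samples")
    if np.any(np.diff(times_s) <= 0):
        raise ValueError("times must be strictly increasing")
    grid = grid or TimeGrid()
    grid_s = grid.values * 60.0
    resampled = np.interp(grid_s, times_s - times_s[0], values, left=0.0, right=0.0)
    peak = resampled.max()
    if peak <= 0:
        return ConcentrationCurve(grid, np.zeros(grid.n_points))
    arrival = int(np.argmax(resampled > arrival_threshold * peak))
    shift = arrival_index - arrival
    aligned = np.zeros(grid.n_points)
    if shift >= 0:
        aligned[shift:] = resampled[: grid.n_points - shift]
    else:
        aligned[: grid.n_points + shift] = resampled[-shift:]
    return ConcentrationCurve(grid, aligned)
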