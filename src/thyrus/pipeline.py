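"""End-to-end study pipeline: simulate → compound → preprocess → segment →
volumetry → observer statistics.

This is the programmatic counterpart of the clinical workflow; the CLI's
`run-study` and the analysis scripts are thin wrappers around
:func:`run_study` and the helpers here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .acquisition import AcquisitionParams
from .compounding import CompoundingParams, VoxelVolume, compound, fill_holes
from .io import RunConfig, write_manifest
from .nn import (
    NetworkConfig,
    SegmentationNet,
    SliceDataset,
    TrainConfig,
    TrainReport,
    build_network,
    dice_score,
    segment_volume,
    train,
)
from .preprocess import apply_geometry, normalize_slices, reorient_axial, resize_center
from .rng import split_rng
from .stats import interobserver_table, intraobserver_variability, paired_t_test, reference_comparison
from .study import SIDES, StudyData, generate_study
from .volumetry import voxel_count_volume

__all__ = [
    "LobeRecon",
    "reconstruct_lobe",
    "analytic_mask_volume",
    "build_slice_dataset",
    "train_study_model",
    "otsu_segment",
    "study_volumes_3d",
    "build_tables",
    "run_study",
]


@dataclass
class LobeRecon:
    """A compounded lobe scan with its slice stack and analytic truth."""

    volume: VoxelVolume
    stack: "SliceStack"
    truth_mask: np.ndarray        # analytic phantom mask on the source grid
    truth_slices: np.ndarray      # truth at network resolution (n, H, W)


def analytic_mask_volume(phantom, volume: VoxelVolume) -> np.ndarray:
    """Ground-truth phantom occupancy at the volume's voxel centres."""
    shape = volume.values.shape
    ii = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    return phantom.contains(volume.index_to_world(ii))


def reconstruct_lobe(study: StudyData, volunteer: int, observer: str, repeat: int,
                     side: str, config: RunConfig) -> LobeRecon:
    """Simulate (or regenerate) one sweep and compound + preprocess it."""
    sweep = study.sweep_for(volunteer, observer, repeat, side)
    cp = CompoundingParams(voxel_spacing=config.voxel_mm, kernel=config.kernel,
                           gaussian_sigma=(0.0, 0.0, config.sweep_smooth_sigma_mm),
                           hole_fill_radius=config.hole_fill_radius)
    vol, wt = compound(sweep, cp)
    vol, wt = fill_holes(vol, wt, cp)
    vol = reorient_axial(vol)
    # crop a fixed physical window about the centroid so the lobe fills a
    # useful fraction of the network's field of view
    window_vox = int(round(config.crop_mm / float(np.mean(vol.spacing[1:]))))
    stack = resize_center(vol, (config.target_hw, config.target_hw), window=window_vox)
    phantom = study.phantoms[(volunteer, side)]
    truth = analytic_mask_volume(phantom, vol)
    truth_slices = apply_geometry(truth.astype(np.float32), stack.geometry, order=0)
    return LobeRecon(vol, stack, truth, truth_slices)


def _select_slices(truth_slices: np.ndarray, k: int, margin: float = 0.15) -> np.ndarray:
    """Evenly sample k slice indices across the lobe's axial extent
    (extended by `margin` so some background-only slices are included)."""
    occupied = np.flatnonzero(truth_slices.reshape(len(truth_slices), -1).any(axis=1))
    n = len(truth_slices)
    if occupied.size == 0:
        lo, hi = 0, n - 1
    else:
        span = occupied[-1] - occupied[0] + 1
        lo = max(0, int(occupied[0] - margin * span))
        hi = min(n - 1, int(occupied[-1] + margin * span))
    return np.unique(np.linspace(lo, hi, min(k, hi - lo + 1)).round().astype(int))


def build_slice_dataset(study: StudyData, config: RunConfig,
                        train_volunteers: list[int], val_volunteers: list[int],
                        observer: str | None = None, repeat: int = 1
                        ) -> tuple[SliceDataset, dict]:
    """Training data from one observer's first-series sweeps, split lobe-wise
    by volunteer.  Returns the dataset plus the per-lobe reconstructions of
    the validation lobes (for 3D evaluation)."""
    observer = observer or study.observers[0].name
    splits = {"train": train_volunteers, "val": val_volunteers}
    images = {"train": [], "val": []}
    masks = {"train": [], "val": []}
    lobes = {"train": [], "val": []}
    recons = {}
    for part, vols in splits.items():
        for v in vols:
            for side in SIDES:
                recon = reconstruct_lobe(study, v, observer, repeat, side, config)
                sel = _select_slices(recon.truth_slices, config.slices_per_lobe)
                images[part].append(normalize_slices(recon.stack.slices[sel]))
                masks[part].append(recon.truth_slices[sel])
                lobes[part].append((v, side))
                recons[(v, observer, repeat, side)] = recon
    ds = SliceDataset(
        np.concatenate(images["train"]), np.concatenate(masks["train"]),
        np.concatenate(images["val"]), np.concatenate(masks["val"]),
        lobes["train"], lobes["val"],
    )
    return ds, recons


def train_study_model(study: StudyData, config: RunConfig
                      ) -> tuple[SegmentationNet, TrainReport, dict]:
    """Train the segmentation network on the study's first-observer scans.

    Volunteers are split train/validation by `config.train_fraction` (lobe-
    wise: both lobes of a volunteer stay on one side of the split).
    """
    vols = study.volunteers
    n_train = max(1, int(round(config.train_fraction * len(vols))))
    if n_train >= len(vols):
        n_train = len(vols) - 1
    rng = split_rng(config.seed, "split")
    order = [int(v) for v in rng.permutation(vols)]
    train_v, val_v = sorted(order[:n_train]), sorted(order[n_train:])
    ds, recons = build_slice_dataset(study, config, train_v, val_v)
    model = build_network(
        NetworkConfig(n_enc_dec=config.n_enc_dec, base_channels=config.base_channels,
                      dropout=config.dropout),
        seed=config.seed,
    )
    tc = TrainConfig(lr=config.lr, batch_size=config.batch_size,
                     max_epochs=config.max_epochs, seed=config.seed)
    model, report = train(model, ds, tc)
    observer = study.observers[0].name
    val_recons = {(v, side): recons[(v, observer, 1, side)]
                  for v in val_v for side in SIDES}
    info = {"train_volunteers": train_v, "val_volunteers": val_v,
            "val_recons": val_recons, "recons": recons, "dataset": ds}
    return model, report, info


def otsu_segment(volume: VoxelVolume) -> VoxelVolume:
    """Classical baseline segmenter: the lobe interior is hypoechoic, so
    threshold below Otsu, clean up morphologically, keep the largest
    component.  Used for fast smoke runs; the network is the study method."""
    from skimage.filters import threshold_otsu

    vals = volume.values
    nz = vals[vals > 0]
    if nz.size == 0:
        return volume.with_values(np.zeros_like(vals, dtype=np.uint8))
    th = threshold_otsu(nz)
    mask = (vals < th) & (vals > 0)
    mask = ndimage.binary_opening(mask, ndimage.generate_binary_structure(3, 1), iterations=2)
    lab, nlab = ndimage.label(mask)
    if nlab > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    return volume.with_values(mask.astype(np.uint8))


def _segment_recon(model: SegmentationNet | None, recon: LobeRecon, config: RunConfig
                   ) -> VoxelVolume:
    if config.segmenter == "otsu" or model is None:
        return otsu_segment(recon.volume)
    return segment_volume(model, recon.stack)


def study_volumes_3d(study: StudyData, config: RunConfig,
                     model: SegmentationNet | None = None,
                     repeats: list[int] | None = None,
                     recon_cache: dict | None = None) -> pd.DataFrame:
    """3D (voxel-count) total volumes for every (volunteer, observer, repeat).

    `recon_cache` maps (volunteer, observer, repeat, side) to an existing
    LobeRecon (e.g. from training) to avoid recompounding those sweeps.
    """
    repeats = repeats or list(range(1, study.n_repeats + 1))
    recon_cache = recon_cache or {}
    rows = []
    for v in study.volunteers:
        for obs in study.observers:
            for rep in repeats:
                tot = 0.0
                for side in SIDES:
                    recon = recon_cache.get((v, obs.name, rep, side))
                    if recon is None:
                        recon = reconstruct_lobe(study, v, obs.name, rep, side, config)
                    mask = _segment_recon(model, recon, config)
                    tot += voxel_count_volume(mask, observer=obs.name, repeat=rep,
                                              side=side).volume
                rows.append({"volunteer": v, "observer": obs.name, "repeat": rep,
                             "modality": "3D", "volume_ml": tot,
                             "reference_ml": float(study.reference[v])})
    return pd.DataFrame(rows)


def build_tables(study_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """The study's three report tables from a combined 2D+3D study table.

    table1: intraobserver CV% per observer and modality, with a paired
    t-test comparing each observer's per-volunteer averaged 2D vs 3D sets;
    table2: pairwise interobserver agreement per modality;
    table3: per-observer comparison against the reference volume.
    """
    t1_rows = []
    for obs, g in study_table.groupby("observer"):
        row = {"observer": obs}
        means = {}
        for modality in ("2D", "3D"):
            gm = g[g["modality"] == modality]
            if gm.empty or gm.groupby("volunteer")["volume_ml"].count().min() < 2:
                continue
            series = gm.set_index("volunteer")["volume_ml"]
            mean_cv, sd_cv, _ = intraobserver_variability(series)
            row[f"cv_mean_{modality.lower()}_pct"] = mean_cv
            row[f"cv_sd_{modality.lower()}_pct"] = sd_cv
            means[modality] = gm.groupby("volunteer")["volume_ml"].mean()
        if len(means) == 2:
            a, b = means["2D"].align(means["3D"], join="inner")
            tt = paired_t_test(a.values, b.values)
            row["p_2d_vs_3d"] = tt.p
            row["significant"] = tt.significant
        t1_rows.append(row)
    table1 = pd.DataFrame(t1_rows)

    table2 = pd.concat(
        [interobserver_table(study_table, m) for m in ("2D", "3D")
         if (study_table["modality"] == m).any()],
        ignore_index=True,
    )
    table3 = pd.concat(
        [reference_comparison(study_table, m) for m in ("2D", "3D")
         if (study_table["modality"] == m).any()],
        ignore_index=True,
    )
    return {"table1": table1, "table2": table2, "table3": table3}


def bland_altman_plots(study_table: pd.DataFrame, out_dir: Path) -> list[Path]:
    """Pairwise interobserver Bland–Altman plots (first series), per modality."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .stats import bland_altman

    paths = []
    for modality in ("2D", "3D"):
        sub = study_table[(study_table["modality"] == modality)
                          & (study_table["repeat"] == study_table["repeat"].min())]
        if sub.empty:
            continue
        pivot = sub.pivot_table(index="volunteer", columns="observer", values="volume_ml")
        obs = sorted(pivot.columns)
        pairs = [(a, b) for i, a in enumerate(obs) for b in obs[i + 1:]]
        fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 3.2), squeeze=False)
        for ax, (a, b) in zip(axes[0], pairs):
            ba = bland_altman(pivot[a].values, pivot[b].values)
            mean_ab = (pivot[a].values + pivot[b].values) / 2
            ax.scatter(mean_ab, pivot[a].values - pivot[b].values, s=14)
            for y, ls in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
                ax.axhline(y, color="k", ls=ls, lw=0.8)
            ax.set_title(f"{a} vs {b} ({modality})", fontsize=9)
            ax.set_xlabel("mean volume (ml)")
            ax.set_ylabel("difference (ml)")
        fig.tight_layout()
        p = out_dir / f"bland_altman_{modality.lower()}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        paths.append(p)
    return paths


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline per config; writes tables, plots, report.

    Returns a dict with the tables, the training report (if the network
    segmenter was used) and output paths.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    acq = AcquisitionParams.desk(image_px=config.image_px, pixel_mm=config.pixel_mm,
                                 frame_rate=config.frame_rate)
    study = generate_study(n_volunteers=config.n_volunteers, n_repeats=config.n_repeats,
                           seed=config.seed, acquisition=acq)

    model = None
    report = None
    split_info = {}
    if config.segmenter == "network":
        model, report, info = train_study_model(study, config)
        split_info = {"train_volunteers": info["train_volunteers"],
                      "val_volunteers": info["val_volunteers"]}

    vols_3d = study_volumes_3d(study, config, model)
    study_table = pd.concat([study.table_2d, vols_3d], ignore_index=True)
    tables = build_tables(study_table)

    files = []
    table_path = out / "study_table.csv"
    study_table.to_csv(table_path, index=False, float_format="%.6g")
    files.append(table_path)
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6g")
        files.append(p)
    files.extend(bland_altman_plots(study_table, out))
    if report is not None:
        p = out / "train_report.json"
        p.write_text(json.dumps({**report.to_dict(), **split_info}, indent=2))
        files.append(p)
    write_manifest(out, config, files)
    return {"tables": tables, "study_table": study_table, "report": report,
            "output_dir": out, "files": files}
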