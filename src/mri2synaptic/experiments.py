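"""Evaluation design: stratified k-fold CV with low-dose-always-test,
leave-one-disease-out, and report generation.

Low-injected-dose participants are never trained or validated on: they sit
in every fold's test set and are aggregated separately, mirroring the
published design where the five low-dose scans were "evaluated repeatedly"
but excluded from training.

The published fold sizes (130 train / 7 validation / 23 test from a cohort
of 160 with 5 fixed-test low-dose ids) cannot form a disjoint exact-coverage
partition over 10 folds, so two modes are provided: the default rotates the
eligible ids through a k-way partition (test sizes as equal as possible,
every participant tested exactly once), and ``strict_sizes`` tops test sets
up by resampling eligible ids so every fold has exactly the configured
sizes (a participant may then be tested in more than one fold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as M
from .nn import NetworkConfig
from .inference import admissible_tile_shape, plan_tiles, predict_volume
from .phantom import PhantomCase
from .preprocess import DVRInputs, apply_mask, combine_brain_mask, compute_dvr
from .training import TrainingConfig, train
from .volume import Volume


@dataclass
class FoldSplit:
    """Disjoint train/validation/test id sets for one fold."""

    fold: int
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]

    def __post_init__(self):
        tr, va, te = set(self.train_ids), set(self.val_ids), set(self.test_ids)
        if tr & va or tr & te or va & te:
            raise ValueError(f"fold {self.fold}: train/val/test sets overlap")


def _apportion(total: int, proportions: pd.Series, available: pd.Series | None = None
               ) -> pd.Series:
    """Apportion ``total`` by group proportions, within one of each target.

    Counts satisfy |count - total * p| <= 1 and never exceed the available
    pool; raises when no such apportionment exists.
    """
    raw = proportions * total
    lo = np.ceil(raw - 1).astype(int).clip(lower=0)
    hi = np.floor(raw + 1).astype(int)
    if available is not None:
        hi = np.minimum(hi, available.reindex(raw.index).fillna(0).astype(int))
    if (lo > hi).any() or lo.sum() > total or hi.sum() < total:
        raise ValueError(
            f"infeasible stratification: need {total} with per-group bounds "
            f"{dict(zip(raw.index, zip(lo, hi)))}"
        )
    counts = lo.copy()
    order = (raw - lo).sort_values(ascending=False).index
    short = total - counts.sum()
    while short > 0:
        for g in order:
            if short == 0:
                break
            if counts[g] < hi[g]:
                counts[g] += 1
                short -= 1
    return counts


def make_folds(manifest: pd.DataFrame, k: int, sizes: tuple[int, int, int],
               seed: int, strict_sizes: bool = True) -> list[FoldSplit]:
    """Build k stratified folds with low-dose ids always and only in test.

    Eligible (non-low-dose) ids are dealt per diagnosis into k base test
    groups, guaranteeing every eligible participant is tested at least once.
    Training sets are drawn by largest-remainder apportionment of the cohort
    diagnosis proportions, so each fold's train composition is within one
    participant of the cohort's.  With ``strict_sizes`` every fold has
    exactly ``sizes`` = (train, val, test) participants.
    """
    n_train, n_val, n_test = sizes
    low = list(manifest.loc[manifest["low_dose"], "id"])
    eligible = manifest.loc[~manifest["low_dose"]]
    n = len(manifest)
    if len(low) > n_test:
        raise ValueError(
            f"infeasible sizes: {len(low)} low-dose ids exceed test size {n_test}"
        )
    rng = np.random.default_rng(int(seed) % 2**31)
    props = manifest["diagnosis"].value_counts(normalize=True)
    slots = n_test - len(low)  # eligible test slots per fold

    groups: list[list[str]]
    if not strict_sizes or k * slots >= len(eligible):
        # deal eligible ids per diagnosis round-robin into k base test groups:
        # every eligible participant is tested at least once
        groups = [[] for _ in range(k)]
        offset = 0
        for diag in sorted(eligible["diagnosis"].unique()):
            ids = list(eligible.loc[eligible["diagnosis"] == diag, "id"])
            rng.shuffle(ids)
            for i, cid in enumerate(ids):
                groups[(offset + i) % k].append(cid)
            offset += len(ids)
    else:
        # a k-fold rotation cannot cover all eligible ids within the test
        # sizes (e.g. a single holdout split); draw stratified test subsets
        test_counts = _apportion(slots, eligible["diagnosis"].value_counts(normalize=True))
        groups = []
        for _ in range(k):
            g: list[str] = []
            for diag, cnt in test_counts.items():
                ids = list(eligible.loc[eligible["diagnosis"] == diag, "id"])
                rng.shuffle(ids)
                g.extend(ids[:cnt])
            groups.append(g)

    folds = []
    eligible_ids = list(eligible["id"])
    for f in range(k):
        test = list(groups[f]) + low
        if strict_sizes:
            if len(test) > n_test:
                raise ValueError(
                    f"infeasible sizes: fold {f} base test set has {len(test)} ids "
                    f"but test size is {n_test}; increase k or test size"
                )
            extra_pool = [c for c in eligible_ids if c not in set(test)]
            rng.shuffle(extra_pool)
            test = test + extra_pool[: n_test - len(test)]
        pool = manifest.loc[~manifest["id"].isin(set(test) | set(low))]
        avail_counts = pool["diagnosis"].value_counts()
        try:
            train_counts = _apportion(n_train, props, avail_counts)
        except ValueError as exc:
            raise ValueError(f"infeasible sizes at fold {f}: {exc}") from exc
        train_ids: list[str] = []
        for diag, cnt in train_counts.items():
            avail = list(pool.loc[pool["diagnosis"] == diag, "id"])
            rng.shuffle(avail)
            train_ids.extend(avail[:cnt])
        val_ids = [c for c in pool["id"] if c not in set(train_ids)]
        if strict_sizes and (len(train_ids), len(val_ids)) != (n_train, n_val):
            raise ValueError(
                f"infeasible sizes: fold {f} yields train/val "
                f"{len(train_ids)}/{len(val_ids)}, expected {n_train}/{n_val}"
            )
        folds.append(FoldSplit(f, sorted(train_ids), sorted(val_ids), sorted(test)))
    return folds


def leave_one_disease_out(manifest: pd.DataFrame, held_out: str, seed: int = 0,
                          val_fraction: float = 0.05) -> FoldSplit:
    """Train on three diagnostic groups, test on the fourth.

    Low-dose ids never enter training or validation: those with the held-out
    diagnosis are tested, the others are excluded from the split entirely.
    """
    if held_out not in set(manifest["diagnosis"]):
        raise ValueError(f"diagnosis {held_out!r} not present in the manifest")
    test = sorted(manifest.loc[manifest["diagnosis"] == held_out, "id"])
    rest = manifest.loc[(manifest["diagnosis"] != held_out) & (~manifest["low_dose"])]
    if rest.empty:
        raise ValueError("holding out this diagnosis empties the training set")
    rng = np.random.default_rng(int(seed) % 2**31)
    val_ids: list[str] = []
    for diag in sorted(rest["diagnosis"].unique()):
        ids = list(rest.loc[rest["diagnosis"] == diag, "id"])
        rng.shuffle(ids)
        n_val = max(1, round(val_fraction * len(ids))) if len(ids) > 1 else 0
        val_ids.extend(ids[:n_val])
    train_ids = sorted(set(rest["id"]) - set(val_ids))
    return FoldSplit(0, train_ids, sorted(val_ids), test)


@dataclass
class PreparedCase:
    """Masked, normalized model inputs/targets derived from one case."""

    id: str
    diagnosis: str
    low_dose: bool
    t1_norm: np.ndarray
    dvr_measured: np.ndarray  # from the noisy BP_ND (the trainable target)
    dvr_clean: np.ndarray  # from the noiseless BP_ND (synthetic-only reference)
    mask: np.ndarray
    atlas: np.ndarray
    roi_names: dict[int, str]
    voxel_size: tuple[float, float, float]


def prepare_case(case: PhantomCase, mask_threshold: float = 0.5,
                 norm_percentile: float = 99.0) -> PreparedCase:
    """Brain-mask, compute DVR targets, and normalize the T1 input.

    The T1 is divided by its within-mask ``norm_percentile`` intensity so
    inputs are bounded near [0, 1] regardless of scanner-analog scaling.
    """
    mask = combine_brain_mask(case.gm, case.wm, case.csf, mask_threshold)
    dvr_meas = apply_mask(
        compute_dvr(DVRInputs(case.bpnd_noisy, case.atlas, case.reference_label)), mask
    )
    dvr_clean = apply_mask(
        compute_dvr(DVRInputs(case.bpnd_clean, case.atlas, case.reference_label)), mask
    )
    t1 = apply_mask(case.t1, mask).values.astype(np.float32)
    inside = t1[mask.values > 0]
    scale = float(np.percentile(inside, norm_percentile)) if inside.size else 1.0
    t1 = t1 / max(scale, 1e-9)
    names = dict(zip(case.roi_table["label"].astype(int), case.roi_table["name"]))
    return PreparedCase(
        id=case.id, diagnosis=case.diagnosis,
        low_dose=bool(getattr(case, "low_dose", False)),
        t1_norm=t1,
        dvr_measured=dvr_meas.values.astype(np.float32),
        dvr_clean=dvr_clean.values.astype(np.float32),
        mask=mask.values.astype(bool),
        atlas=case.atlas.values,
        roi_names=names,
        voxel_size=case.t1.voxel_size,
    )


def _score_case(pc: PreparedCase, pred: np.ndarray, fold: int) -> dict:
    row = {"fold": fold, "id": pc.id, "diagnosis": pc.diagnosis, "low_dose": pc.low_dose}
    for tag, ref in (("", pc.dvr_measured), ("_clean", pc.dvr_clean)):
        row[f"mse{tag}"] = M.mse(ref, pred, pc.mask)
        row[f"ssim{tag}"] = M.ssim_global(ref, pred, pc.mask)
        row[f"bias{tag}"] = M.percent_bias(ref, pred, pc.mask)
        row[f"rho{tag}"] = M.pearson(ref, pred, pc.mask)
    return row


@dataclass
class ExperimentReport:
    """Per-participant rows plus aggregation helpers (mean +/- SD tables)."""

    per_participant: pd.DataFrame
    roi_rows: pd.DataFrame
    loss_curves: dict[int, "pd.DataFrame"] = field(default_factory=dict)

    METRIC_COLS = ("bias", "mse", "ssim", "rho")

    def group_table(self, clean: bool = False) -> pd.DataFrame:
        """Whole-image metrics by diagnosis, normal-dose participants only."""
        tag = "_clean" if clean else ""
        cols = [f"{c}{tag}" for c in self.METRIC_COLS]
        df = self.per_participant.loc[~self.per_participant["low_dose"]]
        return M.aggregate_by_group(df, cols)

    def low_dose_table(self, clean: bool = False) -> pd.DataFrame:
        """Whole-image metrics over low-dose participants only."""
        tag = "_clean" if clean else ""
        cols = [f"{c}{tag}" for c in self.METRIC_COLS]
        df = self.per_participant.loc[self.per_participant["low_dose"]]
        return df[cols].agg(["mean", "std"])

    def roi_table(self, value: str = "percent_bias", low_dose: bool = False) -> pd.DataFrame:
        """ROI x diagnosis mean +/- SD table (bias or SSIM), Tables 5-7 layout."""
        df = self.roi_rows.loc[self.roi_rows["low_dose"] == low_dose]
        piv = df.pivot_table(index="diagnosis", columns="roi", values=value,
                             aggfunc=["mean", "std"])
        all_row = df.groupby("roi")[value].agg(["mean", "std"]).T
        return piv, all_row


def run_experiment(cases: list[PhantomCase], manifest: pd.DataFrame,
                   folds: list[FoldSplit], net_cfg: NetworkConfig,
                   train_cfg: TrainingConfig, score_roi: bool = True,
                   tile_input_shape=None,
                   ) -> tuple[ExperimentReport, dict[int, object]]:
    """Train and score every fold of a split design.

    Whole-volume predictions tile with windows of the training patch size by
    default, so inference windows match the input statistics the network was
    optimized on.  Returns the report plus the trained model per fold.
    Training inputs during scoring are audited to be disjoint from training
    ids.
    """
    if tile_input_shape is None:
        tile_input_shape = (train_cfg.patch_size,) * 3
    by_id = {}
    low_flags = dict(zip(manifest["id"], manifest["low_dose"]))
    for case in cases:
        pc = prepare_case(case)
        pc.low_dose = bool(low_flags.get(pc.id, False))
        by_id[pc.id] = pc

    rows, roi_rows, models, curves = [], [], {}, {}
    for split in folds:
        leak = set(split.train_ids) & set(split.test_ids)
        if leak:
            raise RuntimeError(f"fold {split.fold}: data leakage for ids {sorted(leak)}")
        train_pairs = [(by_id[i].t1_norm, by_id[i].dvr_measured) for i in split.train_ids]
        val_pairs = [(by_id[i].t1_norm, by_id[i].dvr_measured) for i in split.val_ids]
        cfg = TrainingConfig(**{**train_cfg.__dict__})
        cfg.seed = train_cfg.seed + split.fold  # fresh weights per fold
        try:
            model, curve = train(train_pairs, val_pairs, net_cfg, cfg)
        except Exception as exc:  # annotate fold and stage, then abort
            raise RuntimeError(f"fold {split.fold} failed during training: {exc}") from exc
        models[split.fold] = model
        curves[split.fold] = curve.to_frame()
        for cid in split.test_ids:
            pc = by_id[cid]
            plan = plan_tiles(pc.t1_norm.shape, tile_input_shape, net_cfg,
                              output_crop=None)
            pred = predict_volume(model, Volume(pc.t1_norm, pc.voxel_size), plan).values
            pred = np.where(pc.mask, pred, 0.0).astype(np.float32)
            rows.append(_score_case(pc, pred, split.fold))
            if score_roi:
                rep = M.roi_report(pc.dvr_measured, pred, pc.atlas, pc.roi_names)
                rep["fold"], rep["id"] = split.fold, cid
                rep["diagnosis"], rep["low_dose"] = pc.diagnosis, pc.low_dose
                roi_rows.append(rep)
    report = ExperimentReport(
        per_participant=pd.DataFrame(rows),
        roi_rows=pd.concat(roi_rows, ignore_index=True) if roi_rows else pd.DataFrame(),
        loss_curves=curves,
    )
    return report, models


def run_crossval(cases, manifest, net_cfg, train_cfg, k: int,
                 sizes: tuple[int, int, int], seed: int,
                 strict_sizes: bool = True, score_roi: bool = True):
    """Stratified k-fold cross-validation with low-dose-always-test."""
    folds = make_folds(manifest, k, sizes, seed, strict_sizes=strict_sizes)
    return run_experiment(cases, manifest, folds, net_cfg, train_cfg, score_roi)


def denoising_comparison(model, low_dose_cases: list[PhantomCase],
                         tile_input_shape=None) -> pd.DataFrame:
    """Per-case MSE of the noisy measurement vs the prediction, both against
    the noiseless reference (the low-dose denoising property)."""
    rows = []
    for case in low_dose_cases:
        if case.bpnd_clean is None:
            raise ValueError(f"case {case.id} lacks a noiseless reference")
        pc = prepare_case(case)
        tin = tile_input_shape or admissible_tile_shape(model.cfg, pc.t1_norm.shape)
        plan = plan_tiles(pc.t1_norm.shape, tin, model.cfg, output_crop=None)
        pred = predict_volume(model, Volume(pc.t1_norm, pc.voxel_size), plan).values
        pred = np.where(pc.mask, pred, 0.0)
        rows.append({
            "id": case.id,
            "mse_noisy_vs_clean": M.mse(pc.dvr_clean, pc.dvr_measured, pc.mask),
            "mse_pred_vs_clean": M.mse(pc.dvr_clean, pred, pc.mask),
        })
    return pd.DataFrame(rows)
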