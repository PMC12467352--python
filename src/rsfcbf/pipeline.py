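"""End-to-end orchestration of the synthetic study.

``run_synthetic_study`` wires every stage together: simulate a cohort on a
ribbon phantom, extract spectral features in both model modes, split the
cohort balanced on age and sex, train the SVR per mode on the training
subjects, predict the held-out subjects voxel by voxel, reduce predictions
and measurements to regional tables, correlate them across test subjects,
compare the two modes region by region with Fisher r-to-z, and compute
case-control effect sizes plus the cross-map agreement statistic.

Every stage draws its randomness from a named substream of one master seed,
so a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import groups as grp
from . import regional
from .model import (ModelConfig, TrainedCBFModel, assemble_training_set,
                    split_cohort, tune_and_train, predict_voxelwise)
from .spectral import BandSchema, extract_features
from .synthetic import (GenerativeParams, Phantom, PhantomSpec, SyntheticSubject,
                        make_phantom, simulate_cohort)
from .volumes import write_manifest, write_sidecar, write_table

__all__ = ["StudyConfig", "StudyResult", "run_synthetic_study",
            "subject_features", "regional_table", "substream"]

MODES = ("original", "pva_corrected")


def substream(master_seed: int, name: str) -> int:
    """Deterministic named child seed (< 2**31) of a master seed."""
    digest = zlib.crc32(name.encode())
    seq = np.random.SeedSequence([int(master_seed), digest])
    return int(seq.generate_state(1)[0] % (2 ** 31))


@dataclass
class StudyConfig:
    """Everything a full synthetic run needs; defaults are study-scale-free."""

    n_case: int = 0
    n_control: int = 24
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    params: GenerativeParams = field(default_factory=GenerativeParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    train_fraction: float = 2.0 / 3.0
    modes: tuple[str, ...] = MODES
    seed: int = 0


@dataclass
class StudyResult:
    phantom: Phantom
    manifest: pd.DataFrame
    split: object
    models: dict                      # mode -> TrainedCBFModel
    regional_r: dict                  # mode -> DataFrame (region, r, p, n)
    mean_regional_r: dict             # mode -> float (whole-brain row excluded)
    comparison: pd.DataFrame | None   # Fisher r-to-z per region
    voxel_r: dict                     # mode -> pooled held-out voxel-level r
    effect_sizes: dict                # name -> EffectSizeTable DataFrame
    agreement: object | None          # AgreementResult or None
    measured_tables: pd.DataFrame     # subjects x regions, measured CBF
    predicted_tables: dict            # mode -> subjects x regions, predicted


def subject_features(subj: SyntheticSubject, phantom: Phantom, mode: str,
                     schema: BandSchema | None = None):
    """Feature matrix plus measured-CBF target map for one subject."""
    fm = extract_features(subj.bold, phantom.mask, subj.occupancy, mode=mode,
                          schema=schema, allow_partial=True,
                          subject_id=subj.subject_id)
    return fm, subj.measured_cbf


def regional_table(volumes: dict, phantom: Phantom,
                   bilateral: bool = True) -> tuple[pd.DataFrame, pd.Series]:
    """Subjects x regions table plus mask-wide subject means.

    ``volumes`` maps subject_id -> Volume3D on the phantom grid.
    """
    rows, wb = {}, {}
    mask = phantom.mask.data.astype(bool)
    for sid, vol in volumes.items():
        rows[sid] = regional.regionalize(vol, phantom.atlas, phantom.mask,
                                         bilateral=bilateral)
        wb[sid] = float(vol.data[mask].mean())
    table = pd.DataFrame(rows).T
    table.index.name = "subject_id"
    return table, pd.Series(wb, name="whole_brain")


def run_synthetic_study(config: StudyConfig) -> StudyResult:
    """Execute simulate -> features -> split -> train -> predict -> stats."""
    seed = config.seed
    phantom = make_phantom(config.phantom)
    subjects, manifest = simulate_cohort(
        config.n_case, config.n_control, phantom, config.params,
        seed=substream(seed, "cohort"))
    by_id = {s.subject_id: s for s in subjects}

    split = split_cohort(manifest, config.train_fraction,
                         seed=substream(seed, "split"))
    test_ids = split.test_ids

    measured_all, wb_meas_all = regional_table(
        {s.subject_id: s.measured_cbf for s in subjects}, phantom)

    # spectral features are mode-independent: extract once (corrected mode)
    # and derive original-mode matrices by zeroing the occupancy column
    base_feats = {sid: subject_features(by_id[sid], phantom, "pva_corrected",
                                        config.params.schema)
                  for sid in split.train_ids + test_ids}

    models, regional_r, mean_r, predicted_tables = {}, {}, {}, {}
    wb_pred, voxel_r = {}, {}
    mask_arr = phantom.mask.data.astype(bool)
    for mode in config.modes:
        if mode == "pva_corrected":
            feats = base_feats
        else:
            feats = {sid: (fm.as_original(), cbf)
                     for sid, (fm, cbf) in base_feats.items()}
        X, y, groups_ix = assemble_training_set(
            [feats[sid] for sid in split.train_ids],
            voxels_per_subject=config.model.voxels_per_subject,
            seed=substream(seed, f"subsample-{mode}"))
        cfg = replace(config.model, seed=substream(seed, f"cv-{mode}"))
        model = tune_and_train(X, y, cfg, groups=groups_ix,
                               schema=config.params.schema, mode=mode)
        models[mode] = model

        if test_ids:
            preds = {sid: predict_voxelwise(model, feats[sid][0],
                                            phantom.occupancy)
                     for sid in test_ids}
            pooled_pred = np.concatenate([preds[s].data[mask_arr] for s in test_ids])
            pooled_meas = np.concatenate([feats[s][1].data[mask_arr] for s in test_ids])
            voxel_r[mode] = float(np.corrcoef(pooled_pred, pooled_meas)[0, 1])
            pred_tab, wb_p = regional_table(preds, phantom)
            meas_tab = measured_all.loc[pred_tab.index]
            wb_m = wb_meas_all.loc[pred_tab.index]
            stats_tab = regional.predicted_vs_measured(
                pred_tab, meas_tab, whole_brain_pred=wb_p, whole_brain_meas=wb_m)
            regional_r[mode] = stats_tab
            per_region = stats_tab.drop(index=regional.WHOLE_BRAIN)
            mean_r[mode] = float(per_region["r"].mean())
            predicted_tables[mode] = pred_tab
            wb_pred[mode] = wb_p

    comparison = None
    if len(config.modes) == 2 and regional_r:
        orig, corr = (regional_r[m].drop(index=regional.WHOLE_BRAIN)
                      for m in ("original", "pva_corrected"))
        comparison = regional.model_comparison(orig, corr, n1=len(test_ids))

    effect_sizes, agreement = {}, None
    cases = manifest.loc[manifest.group == "case", "subject_id"]
    controls = manifest.loc[manifest.group == "control", "subject_id"]
    if len(cases) >= 2 and len(controls) >= 2:
        effect_sizes["measured"] = grp.cohens_d_table(
            measured_all.loc[cases], measured_all.loc[controls])
        mode = "pva_corrected" if "pva_corrected" in predicted_tables else None
        pred_cases = [c for c in cases if mode and c in predicted_tables[mode].index]
        pred_controls = [c for c in controls if mode and c in predicted_tables[mode].index]
        if mode and len(pred_cases) >= 2 and len(pred_controls) >= 2:
            effect_sizes["predicted"] = grp.cohens_d_table(
                predicted_tables[mode].loc[pred_cases],
                predicted_tables[mode].loc[pred_controls])
            agreement = grp.effect_size_agreement(effect_sizes["predicted"],
                                                  effect_sizes["measured"])

    return StudyResult(phantom, manifest, split, models, regional_r, mean_r,
                       comparison, voxel_r, effect_sizes, agreement,
                       measured_all, predicted_tables)


def write_study_outputs(result: StudyResult, outdir, config: StudyConfig) -> Path:
    """Persist the study's tables with provenance sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {"seed": config.seed, "n_case": config.n_case,
            "n_control": config.n_control,
            "modes": list(config.modes),
            "phantom": asdict(config.phantom)}
    write_manifest(result.manifest, outdir / "manifest.tsv")
    for mode, tab in result.regional_r.items():
        p = write_table(tab.reset_index(), outdir / f"regional_r_{mode}.tsv")
        write_sidecar(p, prov | {"table": f"regional_r_{mode}"})
    if result.comparison is not None:
        p = write_table(result.comparison.reset_index(),
                        outdir / "model_comparison.tsv")
        write_sidecar(p, prov | {"table": "model_comparison"})
    for name, tab in result.effect_sizes.items():
        p = write_table(tab.reset_index(), outdir / f"effect_sizes_{name}.tsv")
        write_sidecar(p, prov | {"table": f"effect_sizes_{name}"})
    if result.agreement is not None:
        write_sidecar(outdir / "agreement", {
            "r": result.agreement.r, "p": result.agreement.p,
            "n_regions": result.agreement.n_regions} | prov)
    return outdir
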