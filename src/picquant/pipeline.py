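"""Cohort-level orchestration: quality control, age grouping, assembly of
the 21-feature table, genotype comparisons, age regressions,
PIC-vs-conductance analyses, non-firing comparisons and PCA reporting.

Cells are the unit of analysis; the animal identifier is carried along
for sensitivity reanalyses but not used by default.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import cclamp, stats, vclamp
from .cclamp import NON_FIRING, REPETITIVE
from .types import CellRecord, RampSpec, StepSpec, TraceSweep

__all__ = [
    "FEATURE_COLUMNS",
    "META_COLUMNS",
    "OPTIONAL_COLUMNS",
    "AGE_GROUPS",
    "assign_age_group",
    "compute_rmp",
    "qc_filter",
    "extract_cell",
    "build_feature_table",
    "compare_groups",
    "nonfiring_comparison",
    "asc_desc_concordance",
    "run_report",
    "IntegrityError",
]

log = logging.getLogger("picquant.pipeline")

META_COLUMNS = ["cell_id", "animal_id", "genotype", "age_days"]

#: the canonical 21 per-cell electrophysiological features
FEATURE_COLUMNS = [
    "input_conductance",        # uS
    "pic_amplitude_asc",        # nA
    "pic_amplitude_desc",       # nA
    "current_transition_spr_pr",  # nA
    "recruitment_current",      # nA
    "derecruitment_current",    # nA
    "freq_transition_spr_pr",   # Hz
    "normalized_pic_desc",      # nA/uS
    "delta_i",                  # nA
    "vthreshold_rel_rmp",       # mV
    "delta_f",                  # Hz
    "pic_peak_voltage_rel_rmp",  # mV
    "fi_gain_desc",             # Hz/nA
    "fi_gain_asc",              # Hz/nA
    "pic_onset_voltage_rel_rmp",  # mV
    "rmp",                      # mV
    "vthreshold",               # mV
    "pic_peak_voltage",         # mV
    "pic_onset_voltage",        # mV
    "pic_end_voltage",          # mV
    "pic_peak_voltage_desc",    # mV
]

OPTIONAL_COLUMNS = ["age_group", "firing_class"]

AGE_GROUPS = ("P30-P60", "P60-P90", "P90-P120")

#: concordance pairs: feature measured on the ascending vs descending limb
ASC_DESC_PAIRS = {
    "pic_amplitude": ("pic_amplitude_asc", "pic_amplitude_desc"),
    "pic_onset_voltage": ("pic_onset_voltage", "pic_end_voltage"),
    "pic_peak_voltage": ("pic_peak_voltage", "pic_peak_voltage_desc"),
    "recruitment_current": ("recruitment_current", "derecruitment_current"),
}

RMP_CUTOFF_MV = -50.0
RMP_DRIFT_MV = 2.0


class IntegrityError(ValueError):
    """Duplicate or inconsistent cell records."""


def assign_age_group(age_days: int) -> str:
    """Half-open age bins: <60 d, 60-89 d, >=90 d."""
    if age_days < 1:
        raise ValueError("age_days must be >= 1")
    if age_days < 60:
        return AGE_GROUPS[0]
    if age_days < 90:
        return AGE_GROUPS[1]
    return AGE_GROUPS[2]


def _baseline_slice(sweep: TraceSweep) -> slice:
    proto = sweep.protocol
    if isinstance(proto, (RampSpec, StepSpec)) and proto.baseline_duration > 0:
        dur = proto.baseline_duration
    else:
        # infer: samples before the command departs from its initial level
        cmd = sweep.command
        tol = 1e-6 * max(1.0, float(np.ptp(cmd)))
        moved = np.flatnonzero(np.abs(cmd - cmd[0]) > tol)
        dur = sweep.time[moved[0]] - sweep.time[0] if moved.size else sweep.duration
    n = int(round(dur * sweep.sampling_rate))
    return slice(0, max(n, 1))


def compute_rmp(cell: CellRecord) -> Tuple[float, float]:
    """RMP (mean voltage over the pre-ramp baseline) and baseline drift
    (peak-to-peak of the 50 ms-smoothed baseline), from the CC ramp."""
    ramps = cell.cc_ramps()
    if not ramps:
        raise ValueError(f"{cell.cell_id}: no CC ramp; cannot measure RMP")
    sweep = ramps[0]
    sl = _baseline_slice(sweep)
    base = sweep.response[sl]
    if base.size < int(0.5 * sweep.sampling_rate):
        log.warning("%s: baseline shorter than 0.5 s", cell.cell_id)
    from scipy.ndimage import uniform_filter1d

    k = max(1, int(round(0.05 * sweep.sampling_rate)))
    sm = uniform_filter1d(base, size=min(k, base.size), mode="nearest")
    return float(np.mean(base)), float(np.ptp(sm))


def qc_filter(cells: Sequence[CellRecord]) -> Tuple[List[CellRecord], List[Tuple[CellRecord, str]]]:
    """Exclude cells with depolarized (> -50 mV) or unstable RMP.

    A cell resting exactly at -50.0 mV is kept: the exclusion rule is
    "more depolarized than -50 mV".  Cells without a current-clamp sweep
    cannot be screened and are kept as-is.
    """
    kept, excluded = [], []
    for cell in cells:
        if cell.rmp is None and cell.cc_ramps():
            rmp, drift = compute_rmp(cell)
            cell.rmp = rmp
        else:
            drift = 0.0
        if cell.rmp is not None and cell.rmp > RMP_CUTOFF_MV:
            excluded.append((cell, "depolarized RMP"))
            continue
        if drift > RMP_DRIFT_MV:
            excluded.append((cell, "unstable RMP"))
            continue
        kept.append(cell)
    for cell, reason in excluded:
        log.info("QC excluded %s: %s", cell.cell_id, reason)
    return kept, excluded


def extract_cell(
    cell: CellRecord,
    pic_config: vclamp.PICConfig = vclamp.PICConfig(),
    spike_config: cclamp.SpikeConfig = cclamp.SpikeConfig(),
    sprpr_config: cclamp.SprPrConfig = cclamp.SprPrConfig(),
) -> dict:
    """Run both measurement chains on one cell and assemble its feature row.

    Voltage-clamp features are present whenever a VC ramp exists; all F-I
    features are missing (NaN) for non-firing cells, mirroring how such
    cells enter the analysis with PIC and conductance values only.
    """
    row = {c: float("nan") for c in FEATURE_COLUMNS}
    row.update(
        cell_id=cell.cell_id,
        animal_id=cell.animal_id,
        genotype=cell.genotype,
        age_days=cell.age_days,
        age_group=assign_age_group(cell.age_days),
        firing_class="",
    )
    vc = cell.vc_ramps()
    if vc:
        pic = vclamp.extract_vclamp(vc[0], pic_config)
        row["input_conductance"] = pic.leak_fit.slope
        row["pic_amplitude_asc"] = pic.amplitude_asc
        row["pic_amplitude_desc"] = pic.amplitude_desc
        row["pic_peak_voltage"] = pic.peak_voltage_asc
        row["pic_peak_voltage_desc"] = pic.peak_voltage_desc
        row["pic_onset_voltage"] = pic.onset_voltage
        row["pic_end_voltage"] = pic.end_voltage
    cc_ramps = cell.cc_ramps()
    if cc_ramps:
        if cell.rmp is None:
            cell.rmp, _ = compute_rmp(cell)
        row["rmp"] = cell.rmp
        steps = cell.cc_steps()
        fi = cclamp.extract_cclamp(
            cc_ramps[0],
            steps[0] if steps else None,
            spike_config,
            sprpr_config,
        )
        row["firing_class"] = fi.firing_class
        if fi.firing_class == REPETITIVE:
            row["recruitment_current"] = fi.recruitment_current
            row["derecruitment_current"] = fi.derecruitment_current
            row["delta_i"] = fi.delta_i
            row["vthreshold"] = fi.v_threshold
            row["current_transition_spr_pr"] = fi.spr_pr_transition_current
            row["freq_transition_spr_pr"] = fi.spr_pr_transition_frequency
            row["fi_gain_asc"] = fi.gain_asc
            row["fi_gain_desc"] = fi.gain_desc
            row["delta_f"] = fi.delta_f
    # derived features; identities hold exactly where both parts exist
    g_in = row["input_conductance"]
    if not math.isnan(g_in) and g_in != 0 and not math.isnan(row["pic_amplitude_desc"]):
        row["normalized_pic_desc"] = row["pic_amplitude_desc"] / g_in
    rmp = row["rmp"]
    if not math.isnan(rmp):
        row["vthreshold_rel_rmp"] = row["vthreshold"] - rmp
        row["pic_peak_voltage_rel_rmp"] = row["pic_peak_voltage"] - rmp
        row["pic_onset_voltage_rel_rmp"] = row["pic_onset_voltage"] - rmp
    return row


def build_feature_table(cells: Sequence[CellRecord], **configs) -> pd.DataFrame:
    """One row per cell, canonical 21-feature schema plus metadata."""
    ids = [c.cell_id for c in cells]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise IntegrityError(f"duplicate cell_id(s): {sorted(dupes)}")
    rows = [extract_cell(c, **configs) for c in cells]
    cols = META_COLUMNS + ["age_group", "firing_class"] + FEATURE_COLUMNS
    table = pd.DataFrame(rows)
    return table[cols]


def _spawn_seed(base: Optional[int], index: int) -> Optional[int]:
    if base is None:
        return None
    return int(np.random.SeedSequence(entropy=base, spawn_key=(index,)).generate_state(1)[0] % (2**31))


def compare_groups(
    table: pd.DataFrame,
    features: Sequence[str] = tuple(FEATURE_COLUMNS),
    n_boot: int = 5000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Effect of genotype (mSOD1 - WT) per feature and age group.

    Returns one row per feature x age group with Hedges' g, its BCa CI
    and Welch statistics; sortable by g within the youngest group, the
    ordering used to rank features by early disease effect.  Groups with
    fewer than 2 cells of either genotype are skipped with a warning.
    """
    if "age_group" not in table.columns:
        table = table.assign(age_group=table["age_days"].map(assign_age_group))
    rows = []
    idx = 0
    for group in AGE_GROUPS:
        sub = table[table["age_group"] == group]
        if sub.empty:
            idx += len(features)
            continue
        for feat in features:
            idx += 1
            wt = sub.loc[sub["genotype"] == "WT", feat].dropna().to_numpy()
            mut = sub.loc[sub["genotype"] == "mSOD1", feat].dropna().to_numpy()
            if wt.size < 2 or mut.size < 2:
                log.warning("skipping %s at %s: too few cells", feat, group)
                continue
            es = stats.hedges_g(wt, mut, n_boot=n_boot, seed=_spawn_seed(seed, idx))
            rows.append({"age_group": group, "feature": feat, **es.to_dict()})
    return pd.DataFrame(rows)


def nonfiring_comparison(
    table: pd.DataFrame, n_boot: int = 5000, seed: Optional[int] = None
) -> dict:
    """Firing vs non-firing comparisons.

    Within mSOD1 cells, input conductance and PIC amplitude of
    repetitively-firing vs non-firing cells (g < 0 means the non-firing
    cells have the smaller values); across genotypes, the age at which
    non-firing cells are encountered.  Classes with fewer than 2 cells
    are skipped.
    """
    if "firing_class" not in table.columns:
        return {}
    out: dict = {}
    mut = table[table["genotype"] == "mSOD1"]
    firing = mut[mut["firing_class"] == REPETITIVE]
    non = mut[mut["firing_class"] == NON_FIRING]
    for i, feat in enumerate(["input_conductance", "pic_amplitude_asc"]):
        a = firing[feat].dropna().to_numpy()
        b = non[feat].dropna().to_numpy()
        if a.size >= 2 and b.size >= 2:
            out[feat] = stats.hedges_g(a, b, n_boot=n_boot, seed=_spawn_seed(seed, i)).to_dict()
    nf = table[table["firing_class"] == NON_FIRING]
    ages_wt = nf.loc[nf["genotype"] == "WT", "age_days"].to_numpy(dtype=float)
    ages_mut = nf.loc[nf["genotype"] == "mSOD1", "age_days"].to_numpy(dtype=float)
    if ages_wt.size >= 2 and ages_mut.size >= 2:
        out["nonfiring_age_days"] = stats.hedges_g(
            ages_wt, ages_mut, n_boot=n_boot, seed=_spawn_seed(seed, 99)
        ).to_dict()
    return out


def asc_desc_concordance(table: pd.DataFrame) -> Dict[str, float]:
    """Squared Pearson correlation between ascending- and descending-limb
    versions of the paired measures (NaN when degenerate)."""
    out = {}
    for name, (a, b) in ASC_DESC_PAIRS.items():
        pairs = table[[a, b]].dropna()
        if len(pairs) < 3 or pairs[a].std() == 0 or pairs[b].std() == 0:
            out[name] = float("nan")
            continue
        r = np.corrcoef(pairs[a], pairs[b])[0, 1]
        out[name] = float(r**2)
    return out


# ---------------------------------------------------------------------------
# end-to-end report
# ---------------------------------------------------------------------------

_REGRESSION_FEATURES = [
    "pic_amplitude_asc",
    "input_conductance",
    "rmp",
    "vthreshold",
    "pic_onset_voltage",
    "pic_peak_voltage",
]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) or math.isinf(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def run_report(
    cohort_spec=None,
    cells: Optional[Sequence[CellRecord]] = None,
    table: Optional[pd.DataFrame] = None,
    out_dir=None,
    seed: int = 0,
    n_boot: int = 5000,
) -> dict:
    """Execute the full pipeline: simulate/load -> QC -> extract -> table
    -> group comparisons -> regressions -> ANCOVA -> PCA.

    Exactly one of ``cohort_spec`` (a SimCohortSpec to simulate),
    ``cells`` or ``table`` must be given.  With ``out_dir`` set, writes
    ``feature_table.csv`` and ``stats.json``; the JSON is byte-identical
    across reruns with the same inputs and seed.
    """
    from .io import write_feature_table

    sources = sum(x is not None for x in (cohort_spec, cells, table))
    if sources != 1:
        raise ValueError("provide exactly one of cohort_spec, cells or table")
    report: dict = {"seed": seed, "n_boot": n_boot}
    if cohort_spec is not None:
        from .synth import sample_cohort

        cells = sample_cohort(cohort_spec, seed=seed)
    if cells is not None:
        kept, excluded = qc_filter(list(cells))
        report["qc"] = {
            "n_input": len(cells),
            "n_kept": len(kept),
            "excluded": [(c.cell_id, reason) for c, reason in excluded],
        }
        table = build_feature_table(kept)
    report["n_cells"] = int(len(table))
    comparisons = compare_groups(table, n_boot=n_boot, seed=seed)
    report["group_comparisons"] = comparisons.to_dict(orient="records")
    report["nonfiring"] = nonfiring_comparison(table, n_boot=n_boot, seed=seed)
    report["asc_desc_r2"] = asc_desc_concordance(table)
    regressions: dict = {}
    for feat in _REGRESSION_FEATURES:
        for geno in ("WT", "mSOD1"):
            sub = table[table["genotype"] == geno][["age_days", feat]].dropna()
            if len(sub) >= 3 and sub["age_days"].nunique() > 1:
                res = stats.regress_vs_age(sub["age_days"], sub[feat])
                regressions[f"{feat}__{geno}"] = asdict(res)
    report["age_regressions"] = regressions
    ancova: dict = {}
    if "age_group" in table.columns:
        for group in AGE_GROUPS:
            sub = table[table["age_group"] == group]
            try:
                ancova[group] = stats.ancova_pic_conductance(sub)
            except ValueError:
                continue
    report["ancova"] = ancova
    try:
        pca = stats.pca_features(table)
        report["pca"] = {
            "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
            "n_components": pca.n_components,
            "n_dropped": pca.n_dropped,
            "loadings": pca.loadings.round(6).to_dict(orient="index"),
        }
    except ValueError as exc:
        report["pca"] = {"error": str(exc)}
    report = _jsonable(report)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_feature_table(table, out_dir / "feature_table.csv")
        with open(out_dir / "stats.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return report
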