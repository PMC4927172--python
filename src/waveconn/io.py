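"""Delimited-text input/output for cohorts and results.

A cohort on disk is a manifest TSV (columns: subject_id, group, file,
tr_seconds) next to one timepoints-by-regions TSV per subject with a
header row of region labels.  The synthetic generator writes the same
format the pipeline reads.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from waveconn.cohort import Cohort, CohortSpec, GroundTruth

__all__ = ["write_cohort", "read_cohort", "read_manifest"]


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Write manifest + per-subject time-series files; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, group, ts in cohort.subjects():
        fname = f"{sid}.tsv"
        df = pd.DataFrame(ts, columns=[f"R{i}" for i in range(ts.shape[1])])
        df.to_csv(outdir / fname, sep="\t", index=False, float_format="%.10g")
        rows.append({"subject_id": sid, "group": group, "file": fname,
                     "tr_seconds": cohort.tr_seconds})
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    gt = cohort.ground_truth
    with open(outdir / "ground_truth.txt", "w") as fh:
        fh.write(gt.describe() + "\n")
        fh.write("module_labels\t"
                 + "\t".join(map(str, gt.module_labels)) + "\n")
    np.savetxt(outdir / "target_control.tsv", gt.target_control,
               delimiter="\t", fmt="%.10g")
    np.savetxt(outdir / "target_patient.tsv", gt.target_patient,
               delimiter="\t", fmt="%.10g")
    return manifest


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group", "file", "tr_seconds"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    return manifest


def read_cohort(manifest_path) -> Cohort:
    """Load a cohort from a manifest TSV and its per-subject files."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    data, ids, groups = [], [], []
    tr = float(manifest["tr_seconds"].iloc[0])
    for _, row in manifest.iterrows():
        ts = pd.read_csv(base / row["file"], sep="\t").to_numpy(dtype=float)
        data.append(ts)
        ids.append(str(row["subject_id"]))
        groups.append(str(row["group"]))
    data = np.array(data)
    n_sub, n_t, n_reg = data.shape
    spec = CohortSpec(n_per_group=groups.count("control"),
                      n_regions=n_reg, n_timepoints=n_t, tr_seconds=tr)
    gt = GroundTruth(
        target_control=np.eye(n_reg), target_patient=np.eye(n_reg),
        module_labels=np.zeros(n_reg, dtype=int), hurst=float("nan"),
        effect_scale=None, group_effect=float("nan"),
    )
    return Cohort(data=data, subject_ids=ids, groups=groups, tr_seconds=tr,
                  ground_truth=gt, spec=spec)
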