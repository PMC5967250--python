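"""End-to-end orchestration: manifests → records → profiles → report → plots.

`run_profile` reads two dataset manifests (set A is the reference, e.g. a
high-resolution crystallographic set; set B the set under scrutiny), extracts
per-residue feature records, and writes per-residue-type npdf tables, (φ,
dBlock) histogram tables and a comparison report.  Everything is plain
delimited text or JSON, so plots are regenerable; given identical inputs and
configuration the numeric outputs are identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .blocktable import BLOCKLESS_RESIDUES, BlockTable, default_block_table
from .exceptions import DistalBlockError, EmptyProfileError
from .profiles import (
    ANGLE_BIN_WIDTH,
    DEFAULT_MIN_RUN,
    DEFAULT_PROMINENCE,
    LENGTH_BIN_WIDTH,
    ComparisonReport,
    build_hist2d,
    compare_sets,
)
from .structure_io import (
    ConformationRecord,
    DatasetManifest,
    apply_selection,
    extract_records,
    read_structure,
    records_to_frame,
    write_records,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ProfileBundle", "extract_manifest", "run_profile",
           "plot_outputs", "PLOT_KINDS"]

PLOT_KINDS = ("scatter3d", "ramachandran_chi1", "npdf", "hist2d")

#: Supported 2D histogram feature pairs; (φ, dBlock) is the default.
HIST2D_PAIRS = (("phi", "dblock"), ("psi", "dblock"), ("phi", "psi"),
                ("phi", "chi1"), ("psi", "chi1"))


@dataclass
class RunConfig:
    """Configuration of one profiling/comparison run."""

    manifest_a: str
    manifest_b: str
    outdir: str
    block_table: Optional[str] = None  # path to a JSON block table
    angle_bin: float = ANGLE_BIN_WIDTH
    length_bin: float = LENGTH_BIN_WIDTH
    prominence: float = DEFAULT_PROMINENCE
    min_run: int = DEFAULT_MIN_RUN
    hist_pair: Tuple[str, str] = ("phi", "dblock")
    seed: int = 0

    def __post_init__(self):
        if self.angle_bin <= 0 or self.length_bin <= 0:
            raise ValueError("bin widths must be positive")
        if tuple(self.hist_pair) not in HIST2D_PAIRS:
            raise ValueError(f"hist_pair must be one of {HIST2D_PAIRS}")

    def load_block_table(self) -> BlockTable:
        if self.block_table is None:
            return default_block_table()
        return BlockTable.from_json(self.block_table)


@dataclass
class ProfileBundle:
    """In-memory results of a run plus the directory they were written to."""

    outdir: Path
    records_a: pd.DataFrame
    records_b: pd.DataFrame
    reports: Dict[str, ComparisonReport]
    skipped: Dict[str, List[str]]  # set label -> skipped structure ids

    @property
    def n_skipped(self) -> int:
        return sum(len(v) for v in self.skipped.values())


def extract_manifest(manifest: DatasetManifest, block_table: BlockTable,
                     label: str = "") -> Tuple[pd.DataFrame, List[str]]:
    """Extract records for every structure in a manifest.

    Unreadable structures are logged and skipped (their ids are returned);
    every manifest entry is accounted for either way.
    """
    records: List[ConformationRecord] = []
    skipped: List[str] = []
    for entry in manifest.entries:
        try:
            chains = read_structure(entry.path)
            residues = apply_selection(chains, manifest.policy)
            recs = extract_records(residues, block_table, source=entry.structure_id)
        except (OSError, DistalBlockError) as exc:
            logger.warning("%s: skipping %s: %s", label, entry.structure_id, exc)
            skipped.append(entry.structure_id)
            continue
        logger.info("%s: %s: %d residue record(s)", label, entry.structure_id,
                    len(recs))
        records.extend(recs)
    if not records:
        raise DistalBlockError(f"{label}: no structure in the manifest was readable")
    return records_to_frame(records), skipped


def run_profile(config: RunConfig,
                policy_a=None, policy_b=None) -> ProfileBundle:
    """Run the full pipeline and write the output bundle.

    Outputs under ``config.outdir``: the two record tables, per-residue-type
    npdf tables (four features, set A as reference), 2D histogram tables for
    both sets, ``comparison.json`` with peak lists and dBlock exceedance
    intervals, and ``run.log`` accounting for every structure.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = config.load_block_table()
    man_a = DatasetManifest.from_csv(config.manifest_a, policy=policy_a)
    man_b = DatasetManifest.from_csv(config.manifest_b, policy=policy_b)

    frame_a, skip_a = extract_manifest(man_a, table, "A")
    frame_b, skip_b = extract_manifest(man_b, table, "B")
    write_records_frame(frame_a, outdir / "records_a.csv")
    write_records_frame(frame_b, outdir / "records_b.csv")

    residue_types = sorted(
        (set(frame_a["res_type"]) | set(frame_b["res_type"])) - BLOCKLESS_RESIDUES)
    reports: Dict[str, ComparisonReport] = {}
    for res_type in residue_types:
        report = compare_sets(frame_a, frame_b, res_type,
                              angle_width=config.angle_bin,
                              length_width=config.length_bin,
                              min_prominence=config.prominence,
                              min_run=config.min_run)
        reports[res_type] = report
        if not report.comparable:
            continue
        for feature, fc in report.features.items():
            frame = pd.DataFrame({
                "bin_center": fc.npdf_a.centers,
                "npdf_a": fc.npdf_a.values,
                "npdf_b": fc.npdf_b.values,
            })
            frame.to_csv(outdir / f"npdf_{res_type}_{feature}.csv", index=False)
        xf, yf = config.hist_pair
        for label, frame in (("a", frame_a), ("b", frame_b)):
            sub = frame[frame["res_type"] == res_type]
            try:
                hist = build_hist2d(
                    sub[xf], sub[yf], xf, yf,
                    x_width=config.angle_bin,
                    y_width=config.length_bin if yf == "dblock" else config.angle_bin,
                    x_limits=(0.0, 360.0),
                    y_limits=None if yf == "dblock" else (0.0, 360.0))
            except EmptyProfileError:
                continue
            hist.to_frame().to_csv(
                outdir / f"hist2d_{res_type}_{xf}_{yf}_{label}.csv", index=False)

    payload = {rt: rep.to_dict() for rt, rep in reports.items()}
    (outdir / "comparison.json").write_text(json.dumps(payload, indent=1) + "\n")
    with open(outdir / "run.log", "w") as fh:
        for label, man, skipped in (("A", man_a, skip_a), ("B", man_b, skip_b)):
            for e in man.entries:
                status = "skipped" if e.structure_id in skipped else "processed"
                fh.write(f"{label}\t{e.structure_id}\t{status}\n")
    return ProfileBundle(outdir=outdir, records_a=frame_a, records_b=frame_b,
                         reports=reports, skipped={"A": skip_a, "B": skip_b})


def write_records_frame(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# plotting (numeric tables are the contract; styling is best-effort)
# ---------------------------------------------------------------------------

def plot_outputs(bundle: ProfileBundle, kinds: Sequence[str] = PLOT_KINDS,
                 outdir=None) -> List[Path]:
    """Render one image per residue type per requested plot kind.

    Kinds: ``scatter3d`` (φ, ψ, χ1 colored by χ1), ``ramachandran_chi1``
    (φ vs ψ colored by χ1), ``npdf`` (overlay of both sets, reference peak at
    1), ``hist2d`` ((φ, dBlock) population-ratio map, modal cell at the top
    of the color scale).  Plot failures are logged, never fatal.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outdir = Path(outdir) if outdir is not None else bundle.outdir / "plots"
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    for res_type, report in bundle.reports.items():
        if not report.comparable:
            continue
        sub_a = bundle.records_a[bundle.records_a["res_type"] == res_type]
        sub_b = bundle.records_b[bundle.records_b["res_type"] == res_type]
        for kind in kinds:
            path = outdir / f"{kind}_{res_type}.png"
            try:
                fig = _plot_one(plt, kind, res_type, report, sub_a, sub_b)
                if fig is None:
                    continue
                fig.savefig(path, dpi=100)
                plt.close(fig)
                written.append(path)
            except Exception as exc:  # non-fatal by contract
                logger.warning("plot %s/%s failed: %s", kind, res_type, exc)
    return written


def _plot_one(plt, kind, res_type, report, sub_a, sub_b):
    if kind == "scatter3d":
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(projection="3d")
        for sub, marker in ((sub_a, "o"), (sub_b, "^")):
            ok = sub[["phi", "psi", "chi1"]].notna().all(axis=1)
            s = sub[ok]
            ax.scatter(s["phi"], s["psi"], s["chi1"], c=s["chi1"],
                       cmap="viridis", vmin=0, vmax=360, s=4, marker=marker)
        ax.set_xlabel("phi (deg)")
        ax.set_ylabel("psi (deg)")
        ax.set_zlabel("chi1 (deg)")
        ax.set_title(f"{res_type}: (phi, psi, chi1)")
        return fig
    if kind == "ramachandran_chi1":
        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True, sharey=True)
        for ax, sub, label in zip(axes, (sub_a, sub_b), ("set A", "set B")):
            ok = sub[["phi", "psi", "chi1"]].notna().all(axis=1)
            s = sub[ok]
            sc = ax.scatter(s["phi"], s["psi"], c=s["chi1"], cmap="viridis",
                            vmin=0, vmax=360, s=4)
            ax.set_xlim(0, 360)
            ax.set_ylim(0, 360)
            ax.set_xlabel("phi (deg)")
            ax.set_title(f"{res_type} {label}")
        axes[0].set_ylabel("psi (deg)")
        fig.colorbar(sc, ax=axes, label="chi1 (deg)")
        return fig
    if kind == "npdf":
        fc = report.features.get("dblock")
        if fc is None:
            return None
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(fc.npdf_a.centers, fc.npdf_a.values, "r-", label="set A (ref)")
        ax.plot(fc.npdf_b.centers, fc.npdf_b.values, "b-", label="set B")
        ax.set_xlabel("dBlock (A)")
        ax.set_ylabel("npdf")
        ax.set_title(f"{res_type}: normalized pdf of dBlock")
        ax.legend()
        return fig
    if kind == "hist2d":
        ok = sub_a[["phi", "dblock"]].notna().all(axis=1)
        s = sub_a[ok]
        if len(s) == 0:
            return None
        h = build_hist2d(s["phi"], s["dblock"])
        fig, ax = plt.subplots(figsize=(6, 4))
        mesh = ax.pcolormesh(h.x_edges, h.y_edges, h.ratio.T, cmap="jet",
                             vmin=0.0, vmax=1.0)
        ax.set_xlabel("phi (deg)")
        ax.set_ylabel("dBlock (A)")
        ax.set_title(f"{res_type}: (phi, dBlock) population ratio, set A")
        fig.colorbar(mesh, label="ratio to modal cell")
        return fig
    raise ValueError(f"unknown plot kind {kind!r}")
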