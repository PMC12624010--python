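"""Per-cell assembly: spot-to-cell assignment, nuclear/cytoplasmic
localization, transcription-site calling, nascent-RNA counting, allelic
classification and the cell-exclusion filters.

The logic follows the smFISH bookkeeping used for T cells: every qc-pass
spot is assigned to the cell outline under its (y, x) position; a spot is
nuclear iff the voxel containing its fitted 3D position carries a nuclear
label belonging to its own cell, otherwise cytoplasmic.  A nuclear object at
least ``tsx_ratio_threshold`` (default 1.5) times brighter than the mean
single-molecule intensity is a transcription site (TsX); its nascent-RNA
count is the intensity ratio rounded half-up with a floor of 1.  Cells in
division (two nuclei in one outline), cells on the field edge, and cells
with miscalled nuclei are flagged and excluded from population statistics
but never dropped from the output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segment import CellOutline2D, NuclearMask3D

log = logging.getLogger("smfish3d")

#: cell_id used for spots over background / segmentation disagreements
ORPHAN = -1

QC_REASONS = ("dividing", "edge", "miscalled_nucleus")


@dataclass
class TranscriptionSite:
    """A DAPI-colocalized high-intensity cluster with its nascent-RNA count."""

    tsx_id: int
    cell_id: int
    channel: str
    position_zyx: tuple[float, float, float]
    integrated_intensity: float
    intensity_ratio: float
    nascent_count: int
    member_spot_ids: list[int] = field(default_factory=list)


@dataclass
class CellRecord:
    """Per-cell assembly across channels.

    ``per_channel`` maps channel name to a dict with keys mature_total,
    mature_nuclear, mature_cytoplasmic, tsx_list, allelic_state.
    """

    cell_id: int
    qc_pass: bool = True
    qc_reasons: list[str] = field(default_factory=list)
    per_channel: dict = field(default_factory=dict)

    def channel(self, name: str) -> dict:
        return self.per_channel.setdefault(name, {
            "mature_total": 0, "mature_nuclear": 0, "mature_cytoplasmic": 0,
            "tsx_list": [], "allelic_state": "none",
        })


# ---------------------------------------------------------------------------
# assignment and localization
# ---------------------------------------------------------------------------

def assign_spots_to_cells(spots: pd.DataFrame, outlines: CellOutline2D) -> pd.DataFrame:
    """Attach ``cell_id`` to each spot from the outline label under its (y, x).

    Spots over background get :data:`ORPHAN` and are excluded from all
    per-cell statistics; the orphan tally is logged per field.
    """
    out = spots.copy()
    ny, nx = outlines.labels.shape
    ids = np.full(len(out), ORPHAN, dtype=int)
    yy = np.clip(np.round(out["y"].to_numpy(float)).astype(int), 0, ny - 1)
    xx = np.clip(np.round(out["x"].to_numpy(float)).astype(int), 0, nx - 1)
    lab = outlines.labels[yy, xx]
    ids[lab > 0] = lab[lab > 0]
    out["cell_id"] = ids
    n_orphan = int((ids == ORPHAN).sum())
    if n_orphan:
        log.info("%d spot(s) over background (orphans)", n_orphan)
    return out


def localize_spots(spots: pd.DataFrame, nuclear_mask: NuclearMask3D,
                   outlines: CellOutline2D | None = None) -> pd.DataFrame:
    """Label each spot nuclear or cytoplasmic by nearest-voxel mask lookup.

    A spot is nuclear iff the voxel containing its position carries a
    nuclear label that belongs to the spot's own cell (when outlines are
    supplied).  A nuclear label belonging to a different cell marks a
    segmentation disagreement: the spot is reassigned to :data:`ORPHAN` and
    logged.  Positions outside the stack are an error.
    """
    out = spots.copy()
    shape = nuclear_mask.labels.shape
    zyx = out[["z", "y", "x"]].to_numpy(float)
    idx = np.round(zyx).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(shape)):
        bad = out.index[(idx < 0).any(axis=1) | (idx >= np.array(shape)).any(axis=1)]
        raise ValueError(f"spot position(s) outside stack bounds: rows {list(bad)}")
    nuc_label = nuclear_mask.labels[idx[:, 0], idx[:, 1], idx[:, 2]]

    compartment = np.where(nuc_label > 0, "nuclear", "cytoplasmic")
    out["compartment"] = compartment
    out["nucleus_label"] = nuc_label

    if outlines is not None and "cell_id" in out.columns:
        nuc_to_cells = {}
        for cell_lab, nucs in outlines.contained_nucleus_ids.items():
            for nid in nucs:
                nuc_to_cells.setdefault(nid, set()).add(cell_lab)
        mism = 0
        for i in out.index[(nuc_label > 0)]:
            nid = int(out.at[i, "nucleus_label"])
            cid = int(out.at[i, "cell_id"])
            owners = nuc_to_cells.get(nid, set())
            if cid not in owners:
                out.at[i, "cell_id"] = ORPHAN
                mism += 1
        if mism:
            log.info("%d nuclear spot(s) over a different cell's nucleus -> orphan",
                     mism)
    return out


# ---------------------------------------------------------------------------
# transcription sites
# ---------------------------------------------------------------------------

def count_nascent(site_intensity: float, mean_intensity: float) -> int:
    """Nascent RNAs at a site: intensity ratio, rounded half-up, floor 1."""
    if site_intensity <= 0 or mean_intensity <= 0:
        raise ValueError("intensities must be positive")
    return max(1, int(math.floor(site_intensity / mean_intensity + 0.5)))


def call_transcription_sites(
    spots: pd.DataFrame,
    nuclear_mask: NuclearMask3D,
    mean_intensity: float,
    tsx_ratio_threshold: float = 1.5,
) -> tuple[list[TranscriptionSite], pd.DataFrame]:
    """Call TsX among nuclear objects and flag their member spots.

    A detected object is a TsX iff it is nuclear (DAPI-colocalized) and its
    integrated intensity is at least ``tsx_ratio_threshold`` times the mean
    single-molecule intensity.  At most two sites are kept per (cell,
    channel) -- the brightest two, one per allele of a diploid genome; any
    further candidates stay flagged as members but the cell's allelic state
    becomes "ambiguous" downstream.  TsX members are removed from the
    mature-mRNA pool via the ``is_tsx_member`` column.
    """
    if mean_intensity <= 0:
        raise ValueError("mean single-molecule intensity must be positive")
    out = spots.copy()
    if "compartment" not in out.columns:
        out = localize_spots(out, nuclear_mask)
    out["is_tsx_member"] = False
    out["intensity_ratio"] = out["integrated_intensity"] / mean_intensity

    sites: list[TranscriptionSite] = []
    ok = out["qc_pass"].astype(bool)
    cand = out[ok & (out["compartment"] == "nuclear")
               & (out["intensity_ratio"] >= tsx_ratio_threshold)]
    if "cell_id" not in cand.columns:
        # no cell assignment yet: group sites by the nucleus they sit in
        cand = cand.assign(cell_id=cand["nucleus_label"].astype(int))
    tsx_id = 0
    for (cell_id, channel), grp in cand.groupby(["cell_id", "channel"], sort=True):
        if cell_id == ORPHAN:
            continue
        grp = grp.sort_values("integrated_intensity", ascending=False)
        for rank, (idx, row) in enumerate(grp.iterrows()):
            out.loc[idx, "is_tsx_member"] = True
            if rank >= 2:
                continue  # extra candidates flagged but not kept as sites
            sites.append(TranscriptionSite(
                tsx_id=tsx_id, cell_id=int(cell_id), channel=str(channel),
                position_zyx=(row["z"], row["y"], row["x"]),
                integrated_intensity=float(row["integrated_intensity"]),
                intensity_ratio=float(row["intensity_ratio"]),
                nascent_count=count_nascent(
                    float(row["integrated_intensity"]), mean_intensity),
                member_spot_ids=[int(row["spot_id"])],
            ))
            tsx_id += 1
    return sites, out


def classify_allelic(n_candidate_sites: int) -> str:
    """0 sites -> none, 1 -> mono, 2 -> bi, more -> ambiguous."""
    if n_candidate_sites < 0:
        raise ValueError("site count must be nonnegative")
    return ("none", "mono", "bi")[n_candidate_sites] \
        if n_candidate_sites <= 2 else "ambiguous"


# ---------------------------------------------------------------------------
# cell assembly and QC filters
# ---------------------------------------------------------------------------

def assemble_cells(
    spots: pd.DataFrame,
    sites: list[TranscriptionSite],
    outlines: CellOutline2D,
    channels: tuple[str, ...] = ("RNA1", "RNA2"),
) -> list[CellRecord]:
    """Build one CellRecord per outline label from localized, TsX-flagged spots."""
    cells = {int(lab): CellRecord(cell_id=int(lab))
             for lab in outlines.stats["label"]}
    ok = spots["qc_pass"].astype(bool) & (spots["cell_id"] != ORPHAN)
    mature = spots[ok & ~spots["is_tsx_member"].astype(bool)]
    for (cid, ch), grp in mature.groupby(["cell_id", "channel"]):
        if int(cid) not in cells or ch not in channels:
            continue
        rec = cells[int(cid)].channel(str(ch))
        rec["mature_nuclear"] = int((grp["compartment"] == "nuclear").sum())
        rec["mature_cytoplasmic"] = int((grp["compartment"] == "cytoplasmic").sum())
        rec["mature_total"] = rec["mature_nuclear"] + rec["mature_cytoplasmic"]

    flagged = spots[ok & spots["is_tsx_member"].astype(bool)]
    n_cand = flagged.groupby(["cell_id", "channel"]).size()
    for cell in cells.values():
        for ch in channels:
            rec = cell.channel(ch)
            rec["tsx_list"] = [s for s in sites
                               if s.cell_id == cell.cell_id and s.channel == ch]
            rec["allelic_state"] = classify_allelic(
                int(n_cand.get((cell.cell_id, ch), 0)))
    return sorted(cells.values(), key=lambda c: c.cell_id)


def apply_cell_filters(
    cells: list[CellRecord],
    outlines: CellOutline2D,
    nuclear_mask: NuclearMask3D,
    volume_bounds: tuple[float, float] = (0.25, 4.0),
    expected_diameter_um: float = 6.0,
) -> list[CellRecord]:
    """Flag dividing, edge and miscalled-nucleus cells; never drop them.

    - "dividing": the outline contains two or more nuclei (cytokinesis).
    - "edge": the outline touches the field border (partially imaged cell).
    - "miscalled_nucleus": nucleus volume outside ``volume_bounds`` times the
      expected-diameter sphere, or nucleus centroid projecting outside the
      cell outline (segmentation failure).

    Reasons accumulate; re-applying the filters is a no-op.
    """
    voxel_um3 = float(np.prod(nuclear_mask.voxel_size_nm)) / 1e9
    expected_vol = math.pi / 6.0 * expected_diameter_um ** 3 / voxel_um3
    lo, hi = volume_bounds
    border = dict(zip(outlines.stats["label"], outlines.stats["touches_border"]))
    nuc_stats = nuclear_mask.stats.set_index("label")
    ny, nx = outlines.labels.shape

    for cell in cells:
        reasons = set(cell.qc_reasons)
        nuc_ids = outlines.contained_nucleus_ids.get(cell.cell_id, [])
        if len(nuc_ids) >= 2:
            reasons.add("dividing")
        if border.get(cell.cell_id, False):
            reasons.add("edge")
        for nid in nuc_ids:
            if nid not in nuc_stats.index:
                reasons.add("miscalled_nucleus")
                continue
            row = nuc_stats.loc[nid]
            if not lo * expected_vol <= row["volume_voxels"] <= hi * expected_vol:
                reasons.add("miscalled_nucleus")
            cy = int(round(row["centroid_y"]))
            cx = int(round(row["centroid_x"]))
            if not (0 <= cy < ny and 0 <= cx < nx) \
                    or outlines.labels[cy, cx] != cell.cell_id:
                reasons.add("miscalled_nucleus")
        cell.qc_reasons = sorted(reasons)
        cell.qc_pass = not reasons
    return cells


# ---------------------------------------------------------------------------
# flattened cell table
# ---------------------------------------------------------------------------

def cells_to_table(cells: list[CellRecord],
                   channels: tuple[str, ...] = ("RNA1", "RNA2")) -> pd.DataFrame:
    """Flatten CellRecords to one row per cell for CSV output and statistics."""
    rows = []
    for cell in cells:
        row = {
            "cell_id": cell.cell_id,
            "qc_pass": cell.qc_pass,
            "qc_reasons": ";".join(cell.qc_reasons),
        }
        for ch in channels:
            rec = cell.channel(ch)
            row[f"{ch}_mature_total"] = rec["mature_total"]
            row[f"{ch}_mature_nuclear"] = rec["mature_nuclear"]
            row[f"{ch}_mature_cytoplasmic"] = rec["mature_cytoplasmic"]
            row[f"{ch}_n_tsx"] = len(rec["tsx_list"])
            row[f"{ch}_nascent_total"] = sum(s.nascent_count for s in rec["tsx_list"])
            row[f"{ch}_allelic_state"] = rec["allelic_state"]
        rows.append(row)
    return pd.DataFrame(rows)
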