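"""Readers and writers for the tabular and structural formats used here.

Tabular data are CSV with explicit headers (TSV auto-detected by file
extension); structures are standard PDB read and written through gemmi.
Readers validate and reject malformed input with row numbers rather than
silently coercing; every writer produces files its matching reader accepts.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .capsid import ShiftSeries
from .dispersion import (DEFAULT_R2EFF_ERRORS, FALLBACK_R2EFF_ERROR,
                         DispersionSeries, compute_r2eff)
from .structures import StructureModel

__all__ = [
    "read_shift_table",
    "write_shift_table",
    "read_dispersion_table",
    "write_dispersion_table",
    "read_binding_shift_table",
    "read_pdb",
    "write_pdb",
    "write_trajectory_pdb",
]

SHIFT_COLUMNS = ["residue", "temperature_K", "gdm_M", "shift_ppm"]
DISPERSION_BASE = ["residue", "field_MHz", "nu_cpmg_Hz"]


class TableFormatError(ValueError):
    """Malformed tabular input (schema, dialect, duplicates)."""


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _read_raw(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    return df


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    """Strict numeric conversion of one column, reporting offending rows.

    Values containing ',' are rejected as a decimal-dialect problem (e.g.
    '1,5' where '1.5' was meant) instead of being coerced.
    """
    raw = df[col].astype(str).str.strip()
    comma = raw.str.contains(",", na=False)
    if comma.any():
        rows = (df.index[comma] + 2).tolist()  # +2: header + 1-based
        raise TableFormatError(
            f"{path}: column {col!r} contains comma decimals (e.g. "
            f"{raw[comma].iloc[0]!r}) at line(s) {rows[:5]}; use '.' as the "
            "decimal separator")
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & raw.notna() & (raw != "nan")
    if bad.any():
        rows = (df.index[bad] + 2).tolist()
        raise TableFormatError(
            f"{path}: column {col!r} has non-numeric value(s) "
            f"(e.g. {raw[bad].iloc[0]!r}) at line(s) {rows[:5]}")
    return vals.to_numpy(dtype=float)


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def read_shift_table(path) -> list[ShiftSeries]:
    """Shift surfaces from CSV/TSV: residue, temperature_K, gdm_M, shift_ppm."""
    df = _read_raw(path)
    _require_columns(df, SHIFT_COLUMNS, path)
    t = _numeric(df, "temperature_K", path)
    g = _numeric(df, "gdm_M", path)
    s = _numeric(df, "shift_ppm", path)
    rid = df["residue"].astype(str).str.strip()
    keys = pd.DataFrame({"r": rid, "t": t, "g": g})
    dup = keys.duplicated()
    if dup.any():
        rows = (df.index[dup] + 2).tolist()
        raise TableFormatError(
            f"{path}: duplicate (residue, temperature, gdm) row(s) at line(s) {rows[:5]}")
    series = []
    for r, grp in pd.DataFrame({"r": rid, "t": t, "g": g, "s": s}).groupby("r", sort=True):
        series.append(ShiftSeries(residue_id=str(r),
                                  records=list(zip(grp["t"], grp["g"], grp["s"]))))
    return series


def write_shift_table(series: list[ShiftSeries], path) -> None:
    rows = [(s.residue_id, t, g, v) for s in series for t, g, v in s.records]
    pd.DataFrame(rows, columns=SHIFT_COLUMNS).to_csv(path, sep=_sep_for(path), index=False)


def read_dispersion_table(path, default_errors: dict | None = None) -> list[DispersionSeries]:
    """Dispersion series from CSV/TSV.

    Either precomputed rates (columns r2eff_s and optionally r2eff_err_s) or
    raw intensities (i_cpmg, i0, t_cpmg_s), converted here. Missing errors
    default per field; non-positive intensities flag the point invalid but
    keep the series.
    """
    df = _read_raw(path)
    _require_columns(df, DISPERSION_BASE, path)
    errors_by_field = dict(DEFAULT_R2EFF_ERRORS)
    if default_errors:
        errors_by_field.update(default_errors)
    rid = df["residue"].astype(str).str.strip()
    field = _numeric(df, "field_MHz", path)
    nu = _numeric(df, "nu_cpmg_Hz", path)
    valid = np.ones(len(df), dtype=bool)
    if "r2eff_s" in df.columns:
        r2 = _numeric(df, "r2eff_s", path)
        if "r2eff_err_s" in df.columns:
            err = _numeric(df, "r2eff_err_s", path)
        else:
            err = np.array([errors_by_field.get(f, FALLBACK_R2EFF_ERROR) for f in field])
    elif {"i_cpmg", "i0", "t_cpmg_s"}.issubset(df.columns):
        i_cpmg = _numeric(df, "i_cpmg", path)
        i0 = _numeric(df, "i0", path)
        t_cpmg = _numeric(df, "t_cpmg_s", path)
        r2 = np.full(len(df), np.nan)
        ok = (i_cpmg > 0) & (i0 > 0)
        valid &= ok
        # t_cpmg may vary per row, so convert row-wise through compute_r2eff
        r2[ok] = [compute_r2eff(ic, i_0, t)
                  for ic, i_0, t in zip(i_cpmg[ok], i0[ok], t_cpmg[ok])]
        err = np.array([errors_by_field.get(f, FALLBACK_R2EFF_ERROR) for f in field])
    else:
        raise TableFormatError(
            f"{path}: need either r2eff_s or (i_cpmg, i0, t_cpmg_s) columns; "
            f"found {list(df.columns)}")
    out = []
    frame = pd.DataFrame({"rid": rid, "field": field, "nu": nu, "r2": r2,
                          "err": err, "valid": valid})
    for (r, f), grp in frame.groupby(["rid", "field"], sort=True):
        out.append(DispersionSeries(
            residue_id=str(r), field=float(f), nu_cpmg=grp["nu"].to_numpy(),
            r2eff=grp["r2"].to_numpy(), err=grp["err"].to_numpy(),
            valid=grp["valid"].to_numpy()))
    return out


def write_dispersion_table(dataset: list[DispersionSeries], path) -> None:
    rows = []
    for s in dataset:
        for nu, r2, err in zip(s.nu_cpmg, s.r2eff, s.err):
            rows.append((s.residue_id, s.field, nu, r2, err))
    pd.DataFrame(rows, columns=DISPERSION_BASE + ["r2eff_s", "r2eff_err_s"]).to_csv(
        path, sep=_sep_for(path), index=False)


def read_binding_shift_table(path) -> dict[str, float]:
    """Per-residue 15N binding shift changes: residue, d15N_free_ppm,
    d15N_bound_ppm (or a single delta_ppm column)."""
    df = _read_raw(path)
    if "delta_ppm" in df.columns:
        _require_columns(df, ["residue"], path)
        delta = _numeric(df, "delta_ppm", path)
    else:
        _require_columns(df, ["residue", "d15N_free_ppm", "d15N_bound_ppm"], path)
        delta = _numeric(df, "d15N_bound_ppm", path) - _numeric(df, "d15N_free_ppm", path)
    rid = df["residue"].astype(str).str.strip()
    return dict(zip(rid, delta))


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_pdb(path, chain: str | None = None, model: int = 0) -> StructureModel:
    """Heavy atoms of one model of a PDB file.

    Hydrogens and waters are dropped; for alternate locations the highest
    occupancy is kept; HETATM residues (e.g. bound nucleotides) are retained
    so ring definitions can apply to them.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if model >= len(st):
        raise ValueError(f"model {model} not present ({len(st)} models)")
    mdl = st[model]
    chains_present = [ch.name for ch in mdl]
    if chain is not None and chain not in chains_present:
        raise ValueError(f"chain {chain!r} not in {path}; available: {chains_present}")
    rows = []
    for ch in mdl:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            if res.name in _WATER_NAMES:
                continue
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for name, atom in best.items():
                rows.append((ch.name, res.seqid.num, res.name, name,
                             atom.element.name, atom.pos.x, atom.pos.y, atom.pos.z))
    if not rows:
        raise ValueError(f"no heavy atoms read from {path}")
    arr = list(zip(*rows))
    return StructureModel(
        chain=np.array(arr[0], dtype=object), resnum=np.array(arr[1]),
        resname=np.array(arr[2], dtype=object), atom_name=np.array(arr[3], dtype=object),
        element=np.array(arr[4], dtype=object),
        coords=np.column_stack([arr[5], arr[6], arr[7]]).astype(float),
        source=str(path))


def _gemmi_model(structure: StructureModel, num: int) -> gemmi.Model:
    # gemmi's add_residue/add_chain copy their argument, so each container
    # must be fully populated before it is added to its parent
    order: list[tuple] = []
    grouped: dict[tuple, list[int]] = {}
    for i in range(structure.n_atoms):
        rkey = (str(structure.chain[i]), int(structure.resnum[i]))
        if rkey not in grouped:
            grouped[rkey] = []
            order.append(rkey)
        grouped[rkey].append(i)
    chains: dict[str, gemmi.Chain] = {}
    chain_order: list[str] = []
    for rkey in order:
        cname = rkey[0]
        if cname not in chains:
            chains[cname] = gemmi.Chain(cname)
            chain_order.append(cname)
        i0 = grouped[rkey][0]
        res = gemmi.Residue()
        res.name = str(structure.resname[i0])
        res.seqid = gemmi.SeqId(rkey[1], " ")
        for i in grouped[rkey]:
            atom = gemmi.Atom()
            atom.name = str(structure.atom_name[i])
            atom.element = gemmi.Element(str(structure.element[i]))
            x, y, z = structure.coords[i]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            atom.occ = 1.0
            res.add_atom(atom)
        chains[cname].add_residue(res)
    mdl = gemmi.Model(num)
    for cname in chain_order:
        mdl.add_chain(chains[cname])
    return mdl


def _structure_to_gemmi(frames: list[StructureModel], name: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    for k, frame in enumerate(frames, start=1):
        st.add_model(_gemmi_model(frame, k))
    st.setup_entities()
    return st


def write_pdb(structure: StructureModel, path) -> None:
    st = _structure_to_gemmi([structure], Path(path).stem)
    st.write_pdb(str(path))


def write_trajectory_pdb(frames: list[StructureModel], path) -> None:
    """Multi-model PDB (one MODEL per frame)."""
    st = _structure_to_gemmi(frames, Path(path).stem)
    st.write_pdb(str(path))


def write_json(obj, path) -> None:
    """Deterministic JSON (sorted keys, fixed float formatting via repr)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (set, tuple)):
        return sorted(x) if isinstance(x, set) else list(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
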