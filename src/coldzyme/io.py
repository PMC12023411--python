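"""Format readers and writers shared by all modules.

Titration series travel as CSV with header columns ``x,y,sigma`` (sigma
optional) and ``#`` comment lines; units are normalised to SI (mol/L,
K) on read via explicit unit suffixes.  SAXS curves are whitespace
three-column text (q [1/A], I, sigma).  Structures are PDB files read
through biotite; alignments are FASTA or A2M (lowercase insert columns
dropped).  Results are reported as JSON, TSV or markdown with the run
configuration and seed embedded.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .evofit import MSA
from .fitting import FitResult, TitrationSeries
from .saxs import BeadStructure, SAXSCurve

__all__ = [
    "read_series",
    "write_series",
    "read_saxs",
    "write_saxs",
    "read_structure",
    "structure_to_beads",
    "read_msa",
    "write_msa",
    "report",
]

#: multiplicative factors to mol/L (concentrations) or offsets handled below.
_CONC_UNITS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "μM": 1e-6, "nM": 1e-9}


def _convert_x(x: np.ndarray, unit: str | None) -> np.ndarray:
    if unit is None:
        return x
    if unit in _CONC_UNITS:
        return x * _CONC_UNITS[unit]
    if unit == "K":
        return x
    if unit in ("C", "degC", "°C"):
        return x + 273.15
    raise ValueError(f"unknown unit {unit!r}")


def read_series(path, x_unit: str | None = None, axis: str = "x") -> TitrationSeries:
    """Read a titration series CSV (columns x, y, optional sigma).

    ``x_unit`` may also be embedded in the file as a comment line
    ``# x_unit: uM``; an explicit argument wins.  Malformed rows raise
    with the offending line number.
    """
    path = Path(path)
    header_unit = None
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    rows = []
    names = None
    for lineno, line in enumerate(lines, start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if body.startswith("x_unit:"):
                header_unit = body.split(":", 1)[1].strip()
            elif body.startswith("spec:"):
                meta["spec"] = json.loads(body.split(":", 1)[1])
            continue
        fields = [f.strip() for f in s.split(",")]
        if names is None:
            names = fields
            if names[0].lower() != "x":
                raise ValueError(f"{path}:{lineno}: expected header starting with 'x'")
            continue
        try:
            rows.append([float(f) for f in fields if f != ""])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed row {s!r}") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    x = _convert_x(arr[:, 0], x_unit or header_unit)
    y = arr[:, 1]
    sigma = arr[:, 2] if arr.shape[1] > 2 else None
    return TitrationSeries(x, y, sigma, axis=axis, meta=meta)


def write_series(series: TitrationSeries, path) -> None:
    """Write a series as CSV; generator spec metadata goes in the header."""
    path = Path(path)
    with open(path, "w") as fh:
        if "spec" in series.meta:
            fh.write(f"# spec: {json.dumps(series.meta['spec'], sort_keys=True)}\n")
        cols = "x,y,sigma" if series.sigma is not None else "x,y"
        fh.write(cols + "\n")
        for i in range(len(series)):
            row = [repr(float(series.x[i])), repr(float(series.y[i]))]
            if series.sigma is not None:
                row.append(repr(float(series.sigma[i])))
            fh.write(",".join(row) + "\n")


def read_saxs(path) -> SAXSCurve:
    """Read a 3-column (q, I, sigma) whitespace text scattering file."""
    data = np.loadtxt(path, comments="#")
    if data.ndim == 1:
        data = data.reshape(1, -1)
    q, I = data[:, 0], data[:, 1]
    sigma = data[:, 2] if data.shape[1] > 2 else None
    return SAXSCurve(q=q, I=I, sigma=sigma)


def write_saxs(curve: SAXSCurve, path) -> None:
    cols = [curve.q, curve.I]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    np.savetxt(path, np.column_stack(cols), header="q[1/A] I[1/cm] sigma[1/cm]")


def read_structure(path, heavy_only: bool = False):
    """Read a PDB file into a biotite AtomArray (first model)."""
    f = pdb.PDBFile.read(str(path))
    arr = f.get_structure(model=1)
    if heavy_only:
        arr = arr[arr.element != "H"]
    return arr


def structure_to_beads(atoms, mode: str = "ca") -> BeadStructure:
    """Coarse-grain an AtomArray to one bead per residue.

    ``mode`` is "ca" (alpha-carbon positions) or "centroid" (mean of
    heavy-atom coordinates per residue).  Uniform unit weights.
    """
    heavy = atoms[atoms.element != "H"]
    coords, res_ids, chain_ids = [], [], []
    for chain in np.unique(heavy.chain_id):
        sub = heavy[heavy.chain_id == chain]
        for rid in np.unique(sub.res_id):
            res = sub[sub.res_id == rid]
            if mode == "ca":
                ca = res[res.atom_name == "CA"]
                if len(ca) == 0:
                    continue
                coords.append(ca.coord[0])
            elif mode == "centroid":
                coords.append(res.coord.mean(axis=0))
            else:
                raise ValueError("mode must be 'ca' or 'centroid'")
            res_ids.append(int(rid))
            chain_ids.append(chain)
    return BeadStructure(
        coords=np.asarray(coords),
        residue_ids=np.asarray(res_ids),
        chain_ids=np.asarray(chain_ids),
    )


def read_msa(path, fmt: str | None = None) -> MSA:
    """Read a FASTA or A2M alignment.

    In A2M, lowercase letters and '.' mark insert columns relative to
    the match states; they are dropped so all rows share the match-state
    length.  '.' in FASTA-style rows is normalised to '-'.
    """
    path = Path(path)
    if fmt is None:
        fmt = "a2m" if path.suffix.lower() in (".a2m",) else "fasta"
    ids, seqs = [], []
    cur_id, cur = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if cur_id is not None:
                    seqs.append("".join(cur))
                    ids.append(cur_id)
                cur_id = line[1:].split()[0]
                cur = []
            else:
                cur.append(line)
    if cur_id is not None:
        seqs.append("".join(cur))
        ids.append(cur_id)
    if fmt == "a2m":
        seqs = ["".join(c for c in s if not (c.islower() or c == ".")) for s in seqs]
    else:
        seqs = [s.upper().replace(".", "-") for s in seqs]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"{path}: mixed alignment lengths {sorted(lengths)}")
    return MSA(sequences=seqs, ids=ids)


def write_msa(msa: MSA, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(msa.ids, msa.sequences):
            fh.write(f">{sid}\n{seq}\n")


def _fit_result_payload(fr: FitResult) -> dict:
    return {
        "estimates": {k: float(v) for k, v in fr.param_estimates.items()},
        "stderr": {
            k: (None if not np.isfinite(v) else float(v))
            for k, v in fr.param_uncertainties.items()
        },
        "reduced_chi2": None if not np.isfinite(fr.reduced_chi2) else float(fr.reduced_chi2),
        "converged": bool(fr.converged),
        "n_obs": fr.n_obs,
        "n_params": fr.n_params,
    }


def format_estimate(value: float, stderr: float | None, digits: int = 2) -> str:
    """Human 'estimate ± stderr' formatting (e.g. '0.23 ± 0.20')."""
    if stderr is None or not np.isfinite(stderr):
        return f"{value:.{digits}f}"
    return f"{value:.{digits}f} ± {stderr:.{digits}f}"


def report(results: dict, path, fmt: str = "json", config: dict | None = None) -> None:
    """Write results with embedded config, seed and package version.

    ``results`` maps names to numbers or FitResult objects.  Formats:
    json (machine-readable), tsv (flat key/value), markdown (human
    summary in estimate ± stderr style).  Field order is deterministic.
    """
    from . import __version__

    payload: dict = {"version": __version__}
    if config is not None:
        payload["config"] = config
    flat: dict = {}
    for name in sorted(results):
        val = results[name]
        flat[name] = _fit_result_payload(val) if isinstance(val, FitResult) else val
    payload["results"] = flat
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")
    elif fmt == "tsv":
        rows = []
        for name, val in flat.items():
            if isinstance(val, dict):
                for k, v in val.get("estimates", {}).items():
                    rows.append((f"{name}.{k}", v))
            else:
                rows.append((name, val))
        pd.DataFrame(rows, columns=["key", "value"]).to_csv(path, sep="\t", index=False)
    elif fmt == "markdown":
        lines = ["# Results", ""]
        if config is not None:
            lines += [f"seed: {config.get('seed', 'n/a')}", ""]
        for name, val in flat.items():
            if isinstance(val, dict):
                lines.append(f"## {name}")
                for k, v in val.get("estimates", {}).items():
                    se = val.get("stderr", {}).get(k)
                    lines.append(f"- {k} = {format_estimate(v, se)}")
                lines.append("")
            else:
                lines.append(f"- {name} = {val}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
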