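"""Peak-list and titration I/O.

Reads and writes assigned 1H-15N HSQC peak lists (CSV/TSV and Sparky-style
``.list`` text) and assembles them, together with a YAML titration config,
into a validated :class:`TitrationSeries`.  Peak matching across titration
points is by assignment (residue id), never by peak geometry.
"""
from __future__ import annotations

import csv
import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Peak",
    "TitrationPoint",
    "TitrationSeries",
    "PeakListError",
    "DuplicateResidueError",
    "TitrationConfigError",
    "read_peak_table",
    "write_peak_table",
    "load_titration",
    "write_csp_table",
    "read_csp_table",
]

# Amide sanity windows (ppm); violations warn, never raise.
H_WINDOW = (5.0, 12.0)
N_WINDOW = (95.0, 140.0)

_AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_AA_3TO1 = {v: k for k, v in _AA_1TO3.items()}

_CSV_HEADER = ["residue_id", "residue_name", "delta_h_ppm", "delta_n_ppm", "height"]
_SPARKY_ASSIGNMENT = re.compile(r"^([A-Za-z?])(\d+)N-?H$")


class PeakListError(ValueError):
    """Malformed or inconsistent peak list."""


class DuplicateResidueError(PeakListError):
    """The same residue id appears twice in one peak list."""


class TitrationConfigError(ValueError):
    """Inconsistent titration configuration."""


@dataclass(frozen=True)
class Peak:
    """One assigned amide resonance at one titration point."""

    residue_id: int
    residue_name: str | None
    delta_h: float
    delta_n: float
    height: float | None = None


@dataclass(frozen=True)
class TitrationPoint:
    """Peak list plus concentrations at one ligand:protein ratio."""

    index: int
    ratio: float
    protein_conc: float  # mM
    ligand_conc: float   # mM
    peaks: dict[int, Peak]


@dataclass
class TitrationSeries:
    points: list[TitrationPoint]
    label: str = ""
    mode: str = "constant-protein"  # or "dilution-corrected"

    def validate(self) -> None:
        if not self.points:
            raise TitrationConfigError("titration has no points")
        ratios = [p.ratio for p in self.points]
        if ratios[0] != 0.0:
            raise TitrationConfigError(
                f"first titration point must have ratio 0, got {ratios[0]}")
        if any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise TitrationConfigError(f"ratios must be strictly increasing: {ratios}")
        for p in self.points:
            expected = p.ratio * p.protein_conc
            if not math.isclose(p.ligand_conc, expected, rel_tol=1e-9, abs_tol=1e-15):
                raise TitrationConfigError(
                    f"point {p.index}: ligand_conc {p.ligand_conc} != "
                    f"ratio*protein_conc {expected}")
        free = set(self.points[0].peaks)
        for p in self.points[1:]:
            extra = set(p.peaks) - free
            if extra:
                warnings.warn(
                    f"point {p.index}: residues {sorted(extra)} absent from the "
                    "free reference; they will be ignored", stacklevel=2)

    @property
    def ratios(self) -> np.ndarray:
        return np.array([p.ratio for p in self.points])

    @property
    def ligand_concs(self) -> np.ndarray:
        return np.array([p.ligand_conc for p in self.points])

    @property
    def protein_concs(self) -> np.ndarray:
        return np.array([p.protein_conc for p in self.points])

    @property
    def residues(self) -> list[int]:
        """Residues of the free reference spectrum, sorted."""
        return sorted(self.points[0].peaks)

    def heights(self, residue_id: int) -> list[float | None]:
        """Per-point peak height for one residue; None where absent."""
        out: list[float | None] = []
        for p in self.points:
            pk = p.peaks.get(residue_id)
            out.append(None if pk is None else pk.height)
        return out


def _open_source(source) -> tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", encoding="utf-8"), True


def _check_windows(peaks: Iterable[Peak], origin: str) -> None:
    for pk in peaks:
        if not (H_WINDOW[0] <= pk.delta_h <= H_WINDOW[1]) or \
           not (N_WINDOW[0] <= pk.delta_n <= N_WINDOW[1]):
            warnings.warn(
                f"{origin}: residue {pk.residue_id} shifts "
                f"({pk.delta_h}, {pk.delta_n}) ppm outside the amide window",
                stacklevel=3)


def _parse_float(tok: str, what: str, lineno: int):
    try:
        return float(tok)
    except ValueError:
        raise PeakListError(f"line {lineno}: cannot parse {what} from {tok!r}") from None


def read_peak_table(source, dialect: str = "csv") -> list[Peak]:
    """Read one assigned peak list.

    ``dialect`` is ``csv``/``tsv`` (header
    ``residue_id,residue_name,delta_h_ppm,delta_n_ppm,height``) or ``sparky``
    (``Assignment w1 w2 [height]`` with w1 = 15N, w2 = 1H).  Duplicate residue
    ids raise; shifts outside the amide sanity window only warn.
    """
    if dialect not in ("csv", "tsv", "sparky"):
        raise ValueError(f"unsupported dialect {dialect!r}")
    stream, close = _open_source(source)
    try:
        name = getattr(stream, "name", "<stream>")
        if dialect == "sparky":
            peaks = _read_sparky(stream, name)
        else:
            peaks = _read_delimited(stream, "\t" if dialect == "tsv" else ",", name)
    finally:
        if close:
            stream.close()
    if not peaks:
        raise PeakListError(f"{name}: empty peak list")
    seen: set[int] = set()
    for pk in peaks:
        if pk.residue_id in seen:
            raise DuplicateResidueError(
                f"{name}: residue {pk.residue_id} appears more than once")
        seen.add(pk.residue_id)
    _check_windows(peaks, name)
    return peaks


def _read_delimited(stream: IO[str], sep: str, name: str) -> list[Peak]:
    reader = csv.reader(stream, delimiter=sep)
    peaks: list[Peak] = []
    header_seen = False
    for lineno, row in enumerate(reader, start=1):
        if not row or all(not c.strip() for c in row):
            continue
        if not header_seen:
            if [c.strip() for c in row] != _CSV_HEADER:
                raise PeakListError(
                    f"{name}: line {lineno}: expected header "
                    f"{','.join(_CSV_HEADER)!r}")
            header_seen = True
            continue
        if len(row) != 5:
            raise PeakListError(f"{name}: line {lineno}: expected 5 fields, got {len(row)}")
        rid_tok, rname, dh_tok, dn_tok, h_tok = (c.strip() for c in row)
        try:
            rid = int(rid_tok)
        except ValueError:
            raise PeakListError(
                f"{name}: line {lineno}: bad residue_id {rid_tok!r}") from None
        dh = _parse_float(dh_tok, "delta_h_ppm", lineno)
        dn = _parse_float(dn_tok, "delta_n_ppm", lineno)
        height = _parse_float(h_tok, "height", lineno) if h_tok else None
        peaks.append(Peak(rid, rname or None, dh, dn, height))
    return peaks


def _read_sparky(stream: IO[str], name: str) -> list[Peak]:
    peaks: list[Peak] = []
    for lineno, line in enumerate(stream, start=1):
        toks = line.split()
        if not toks or toks[0].lower() in ("assignment", "#"):
            continue
        if len(toks) not in (3, 4):
            raise PeakListError(
                f"{name}: line {lineno}: expected 'Assignment w1 w2 [height]'")
        m = _SPARKY_ASSIGNMENT.match(toks[0])
        if not m:
            raise PeakListError(
                f"{name}: line {lineno}: cannot parse assignment {toks[0]!r}")
        one, rid = m.group(1), int(m.group(2))
        rname = _AA_1TO3.get(one.upper())
        dn = _parse_float(toks[1], "w1 (15N)", lineno)
        dh = _parse_float(toks[2], "w2 (1H)", lineno)
        height = _parse_float(toks[3], "height", lineno) if len(toks) == 4 else None
        peaks.append(Peak(rid, rname, dh, dn, height))
    return peaks


def write_peak_table(peaks: Sequence[Peak], dest, dialect: str = "csv") -> None:
    """Write a peak list; inverse of :func:`read_peak_table` (floats are
    written with full shortest-roundtrip precision)."""
    if dialect not in ("csv", "tsv", "sparky"):
        raise ValueError(f"unsupported dialect {dialect!r}")
    if not peaks:
        raise PeakListError("refusing to write an empty peak list")
    stream, close = (dest, False) if hasattr(dest, "write") else \
        (open(dest, "w", encoding="utf-8", newline=""), True)
    try:
        if dialect == "sparky":
            stream.write("      Assignment         w1         w2   Height\n")
            for pk in peaks:
                one = _AA_3TO1.get((pk.residue_name or "").upper(), "?")
                line = f"{one}{pk.residue_id}N-H {pk.delta_n!r} {pk.delta_h!r}"
                if pk.height is not None:
                    line += f" {pk.height!r}"
                stream.write(line + "\n")
        else:
            sep = "\t" if dialect == "tsv" else ","
            writer = csv.writer(stream, delimiter=sep, lineterminator="\n")
            writer.writerow(_CSV_HEADER)
            for pk in peaks:
                writer.writerow([
                    pk.residue_id, pk.residue_name or "",
                    repr(pk.delta_h), repr(pk.delta_n),
                    "" if pk.height is None else repr(pk.height),
                ])
    finally:
        if close:
            stream.close()


def load_titration(config, peak_files: Sequence | None = None,
                   base_dir=None) -> TitrationSeries:
    """Assemble a validated :class:`TitrationSeries`.

    ``config`` is a YAML path or an already-parsed mapping with keys
    ``label``, ``protein_conc_mM`` (scalar or per-point list), ``ratios``,
    ``mode``, ``peak_files``, optional ``dialect``, ``csp_weight``, ``seed``.
    Ligand concentrations are derived as ratio * protein concentration.
    """
    if isinstance(config, (str, Path)):
        cfg_path = Path(config)
        with open(cfg_path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        if base_dir is None:
            base_dir = cfg_path.parent
    else:
        cfg = dict(config)
    base_dir = Path(base_dir) if base_dir is not None else Path(".")

    try:
        ratios = [float(r) for r in cfg["ratios"]]
        protein = cfg["protein_conc_mM"]
    except KeyError as exc:
        raise TitrationConfigError(f"config missing key {exc}") from None
    n = len(ratios)
    if ratios[0] != 0.0:
        raise TitrationConfigError(f"first ratio must be 0, got {ratios[0]}")
    if any(b <= a for a, b in zip(ratios, ratios[1:])):
        raise TitrationConfigError(f"ratios must be strictly increasing: {ratios}")
    protein_list = [float(protein)] * n if np.isscalar(protein) \
        else [float(v) for v in protein]
    if len(protein_list) != n:
        raise TitrationConfigError(
            f"{len(protein_list)} protein concentrations for {n} ratios")

    if peak_files is None:
        peak_files = cfg.get("peak_files")
    if peak_files is None:
        raise TitrationConfigError("no peak files given")
    if len(peak_files) != n:
        raise TitrationConfigError(
            f"{len(peak_files)} peak files for {n} configured points")

    dialect = cfg.get("dialect", "csv")
    points = []
    for i, (ratio, a, pf) in enumerate(zip(ratios, protein_list, peak_files)):
        path = Path(pf)
        if not path.is_absolute():
            path = base_dir / path
        if not path.exists():
            raise FileNotFoundError(f"peak file not found: {path}")
        peaks = read_peak_table(path, dialect=dialect)
        points.append(TitrationPoint(
            index=i, ratio=ratio, protein_conc=a, ligand_conc=ratio * a,
            peaks={pk.residue_id: pk for pk in peaks}))
    series = TitrationSeries(points=points, label=str(cfg.get("label", "")),
                             mode=str(cfg.get("mode", "constant-protein")))
    series.validate()
    return series


def write_csp_table(profiles, series: TitrationSeries, dest) -> None:
    """Write per-residue weighted shift distances as tidy CSV
    (``residue_id,point_index,ratio,ligand_conc_mM,delta_delta_ppm,flag``).
    Missing (intermediate-exchange) points keep an empty value, never 0."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no CSP profiles to write")
    rows = []
    for prof in profiles:
        for i, (dd, flag) in enumerate(zip(prof.delta_delta, prof.flags)):
            rows.append({
                "residue_id": prof.residue_id,
                "point_index": i,
                "ratio": series.points[i].ratio,
                "ligand_conc_mM": series.points[i].ligand_conc,
                "delta_delta_ppm": "" if flag == "missing" else repr(float(dd)),
                "flag": flag,
            })
    pd.DataFrame(rows).to_csv(dest, index=False)


def read_csp_table(source):
    """Inverse of :func:`write_csp_table`; returns ``{residue_id: CSPProfile}``."""
    from .csp import CSPProfile  # local import: avoid a cycle

    df = pd.read_csv(source, dtype={"delta_delta_ppm": str})
    out: dict[int, CSPProfile] = {}
    for rid, grp in df.groupby("residue_id", sort=True):
        grp = grp.sort_values("point_index")
        dd = np.array([float(v) if isinstance(v, str) and v else np.nan
                       for v in grp["delta_delta_ppm"]])
        out[int(rid)] = CSPProfile(residue_id=int(rid), delta_delta=dd,
                                   flags=tuple(grp["flag"]))
    return out
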