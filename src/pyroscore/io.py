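"""File readers and writers: TSV, MatrixMarket, GMT, JSON.

Conventions: TSV with a header row is the canonical tabular dialect, ISO-8601
dates, decimal points. Matrices are oriented samples/cells in rows and
features in columns on read. The aptamer platform's native ADAT container is
not parsed; export the RFU matrix to TSV (samples x proteins, one header row
of protein identifiers) before use — any spreadsheet or the vendor tooling
can do this.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .monitoring import PatientTrajectory
from .pathway import PathwaySpec
from .proteomics import ScoreWeights

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_mtx",
    "read_pathway",
    "write_direction_tsv",
    "write_gmt",
    "read_visits",
    "write_visits",
    "read_weights",
    "write_weights",
    "read_summary",
    "write_summary",
]

_SIGNS = {"+1": 1, "-1": -1, "+": 1, "-": -1, "1": 1, "−1": -1}


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.duplicated().any():
        dups = sorted(set(idx[idx.duplicated()]))
        raise ValueError(f"duplicate {what} identifiers: {dups[:5]}")


def read_matrix(path, fmt: str = "tsv", genes_path=None, cells_path=None):
    """Read a feature matrix; rows are samples/cells, columns features.

    ``fmt='tsv'`` returns a DataFrame (first column is the row index).
    ``fmt='mtx'`` requires the two label files and returns
    ``(sparse matrix, cell_ids, gene_ids)`` oriented cells x genes.
    """
    if fmt == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        _check_unique(header[1:], "feature")  # before pandas mangles duplicates
        df = pd.read_csv(path, sep="\t", index_col=0)
        _check_unique(df.index, "sample")
        return df
    if fmt == "mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("MTX input requires gene and cell label files")
        return read_mtx(path, genes_path, cells_path)
    raise ValueError(f"unknown matrix format {fmt!r}")


def read_mtx(mtx_path, genes_path, cells_path):
    """MatrixMarket matrix + label files, normalized to cells x genes."""
    mat = sp.csr_matrix(scipy.io.mmread(mtx_path))
    genes = [ln.strip().split("\t")[0] for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
    cells = [ln.strip().split("\t")[0] for ln in Path(cells_path).read_text().splitlines() if ln.strip()]
    _check_unique(genes, "gene")
    _check_unique(cells, "cell")
    if mat.shape == (len(cells), len(genes)):
        pass
    elif mat.shape == (len(genes), len(cells)):
        mat = mat.T.tocsr()
    else:
        raise ValueError(
            f"MTX dimensions {mat.shape} match neither "
            f"(cells={len(cells)}, genes={len(genes)}) nor its transpose"
        )
    return mat, cells, genes


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_pathway(path, fmt: str | None = None, name: str | None = None) -> PathwaySpec:
    """Read a pathway from GMT or a two-column gene/direction TSV.

    GMT genes default to +1 directionality pending
    :func:`pyroscore.pathway.assign_directionality`; a direction TSV is
    authoritative. Format inferred from the extension when not given.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gmt" if path.suffix.lower() == ".gmt" else "direction-tsv"
    lines = path.read_text().splitlines()
    if fmt == "gmt":
        for ln_no, line in enumerate(lines, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln_no}: GMT lines need >=3 tab-separated fields")
            set_name, _desc, *genes = fields
            genes = [g for g in genes if g]
            _check_unique(genes, "pathway gene")
            return PathwaySpec.from_directions(
                {g: 1 for g in genes}, name=name or set_name, source="default"
            )
        raise ValueError(f"{path}: empty GMT file")
    if fmt == "direction-tsv":
        directions: dict[str, int] = {}
        for ln_no, line in enumerate(lines, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if ln_no == 1 and fields[0].lower() in ("gene", "symbol"):
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{ln_no}: expected gene<TAB>direction")
            gene, sign = fields[0], fields[1].strip()
            if sign not in _SIGNS:
                raise ValueError(
                    f"{path}:{ln_no}: direction must be one of +1/-1/+/-, got {sign!r}"
                )
            if gene in directions:
                raise ValueError(f"{path}:{ln_no}: duplicate gene {gene!r}")
            directions[gene] = _SIGNS[sign]
        if not directions:
            raise ValueError(f"{path}: no gene/direction rows found")
        return PathwaySpec.from_directions(directions, name=name or path.stem, source="file")
    raise ValueError(f"unknown pathway format {fmt!r}")


def write_direction_tsv(pathway: PathwaySpec, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tdirection\n")
        for g in pathway.genes:
            fh.write(f"{g}\t{pathway.direction_of(g):+d}\n")


def write_gmt(pathway: PathwaySpec, path, description: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("\t".join([pathway.name, description, *pathway.genes]) + "\n")


def read_visits(visits_path, therapy_path=None) -> list[PatientTrajectory]:
    """Visits TSV (patient_id, date, disability, lesions[, on_therapy]) plus
    an optional therapy table (patient_id, therapy_start[, arm])."""
    visits = pd.read_csv(visits_path, sep="\t", parse_dates=["date"])
    therapy_start: dict[str, pd.Timestamp] = {}
    if therapy_path is not None:
        therapy = pd.read_csv(therapy_path, sep="\t", parse_dates=["therapy_start"])
        therapy_start = dict(zip(therapy["patient_id"], therapy["therapy_start"]))
    out = []
    for pid, block in visits.groupby("patient_id", sort=True):
        block = block.sort_values("date").reset_index(drop=True)
        out.append(
            PatientTrajectory(
                patient_id=str(pid),
                visits=block[["date", "disability", "lesions"]],
                therapy_start=therapy_start.get(pid),
            )
        )
    return out


def write_visits(trajectories: list[PatientTrajectory], visits_path, therapy_path=None) -> None:
    rows = []
    for traj in trajectories:
        for _, v in traj.visits.iterrows():
            on = traj.therapy_start is not None and v["date"] >= traj.therapy_start
            rows.append(
                (traj.patient_id, v["date"].date().isoformat(), v["disability"], int(v["lesions"]), on)
            )
    pd.DataFrame(
        rows, columns=["patient_id", "date", "disability", "lesions", "on_therapy"]
    ).to_csv(visits_path, sep="\t", index=False, float_format="%.10g")
    if therapy_path is not None:
        pd.DataFrame(
            [
                (t.patient_id, t.therapy_start.date().isoformat())
                for t in trajectories
                if t.therapy_start is not None
            ],
            columns=["patient_id", "therapy_start"],
        ).to_csv(therapy_path, sep="\t", index=False)


def read_weights(path) -> ScoreWeights:
    """A frozen score-protein weight table from JSON, to apply a published
    score without re-selection."""
    payload = json.loads(Path(path).read_text())
    table = pd.DataFrame(payload["proteins"]).set_index("protein")
    return ScoreWeights(table)


def write_weights(weights: ScoreWeights, path) -> None:
    records = weights.table.reset_index().to_dict(orient="records")
    Path(path).write_text(json.dumps({"proteins": records}, indent=2, default=str) + "\n")


def read_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"cell_type", "gene", "avg_expression", "fraction_expressing"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    return df


def write_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_lines(lines: list[str], path) -> None:
    Path(path).write_text("".join(f"{x}\n" for x in lines))


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.ndarray,)):
            return o.tolist()
        if isinstance(o, pd.Timestamp):
            return o.isoformat()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default, sort_keys=True) + "\n")
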