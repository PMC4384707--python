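"""Readers and writers for the package's plain-text interchange formats.

Everything is TSV or YAML: time-activity curves, nuclide spectra, organ
geometries, expression matrices and sample sheets (plus the table block
of a GEO series-matrix file), per-condition differential-expression
calls, transcript->GO annotations (2-column TSV or a GAF 2.x subset)
and GO-term category maps.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from atdose.diffexpr import ExpressionStudy, SAMPLE_COLUMNS, Condition
from atdose.dosimetry import NuclideAlphaSpectrum, OrganGeometry, TimeActivityCurve
from atdose.profiles import AnnotationMap

# ---------------------------------------------------------------- dosimetry


def read_curves_tsv(path) -> list[TimeActivityCurve]:
    """Curves TSV with header ``organ  time_h  activity_bq  decay_corrected``."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for organ, grp in df.groupby("organ", sort=True):
        grp = grp.sort_values("time_h")
        flags = set(grp["decay_corrected"].astype(bool))
        if len(flags) != 1:
            raise ValueError(f"organ {organ!r}: mixed decay_corrected flags")
        out.append(
            TimeActivityCurve(
                organ=str(organ),
                times_h=grp["time_h"].to_numpy(float),
                activities_bq=grp["activity_bq"].to_numpy(float),
                decay_corrected=flags.pop(),
            )
        )
    return out


def write_curves_tsv(curves: Iterable[TimeActivityCurve], path) -> None:
    rows = []
    for c in curves:
        for t, a in zip(c.times_h, c.activities_bq):
            rows.append(
                {"organ": c.organ, "time_h": t, "activity_bq": a,
                 "decay_corrected": c.decay_corrected}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_nuclide_yaml(path) -> NuclideAlphaSpectrum:
    """Nuclide file: ``half_life_h`` plus a ``lines`` list of
    ``{yield, energy_mev}`` entries."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    lines = tuple((float(l["yield"]), float(l["energy_mev"])) for l in doc["lines"])
    return NuclideAlphaSpectrum(lines=lines, half_life_h=float(doc["half_life_h"]))


def read_organs_tsv(path) -> list[OrganGeometry]:
    """Organ TSV: ``organ  mass_kg  absorbed_fraction`` (fraction optional)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        phi = float(getattr(row, "absorbed_fraction", 1.0))
        out.append(OrganGeometry(organ=str(row.organ), mass_kg=float(row.mass_kg),
                                 absorbed_fraction=phi))
    return out


def write_organs_tsv(geometries: Iterable[OrganGeometry], path) -> None:
    pd.DataFrame(
        [{"organ": g.organ, "mass_kg": g.mass_kg,
          "absorbed_fraction": g.absorbed_fraction} for g in geometries]
    ).to_csv(path, sep="\t", index=False)


def parse_windows(spec: str) -> list[tuple[float, float]]:
    """Parse ``"1.7:1,1.7:6,105:1"`` into (activity_kbq, t_end_h) pairs."""
    out = []
    for part in spec.split(","):
        act, t = part.strip().split(":")
        out.append((float(act), float(t)))
    return out


# --------------------------------------------------------------- expression


def read_matrix_tsv(path) -> pd.DataFrame:
    """Expression TSV: first column probe ids, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "probe"
    return df


def read_samples_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet lacks columns {missing}")
    df["is_control"] = df["is_control"].astype(bool)
    return df


def read_expression_study(matrix_path, samples_path, probe_gene_path=None) -> ExpressionStudy:
    probe_gene = None
    if probe_gene_path is not None:
        pg = pd.read_csv(probe_gene_path, sep="\t")
        probe_gene = pd.Series(pg.iloc[:, 1].to_numpy(), index=pg.iloc[:, 0].to_numpy())
    return ExpressionStudy(
        matrix=read_matrix_tsv(matrix_path),
        samples=read_samples_tsv(samples_path),
        probe_gene=probe_gene,
    )


def write_expression_study(study: ExpressionStudy, matrix_path, samples_path,
                           probe_gene_path=None) -> None:
    study.matrix.to_csv(matrix_path, sep="\t")
    study.samples.to_csv(samples_path, sep="\t", index=False)
    if probe_gene_path is not None and study.probe_gene is not None:
        study.probe_gene.rename("gene").rename_axis("probe").to_csv(
            probe_gene_path, sep="\t"
        )


def read_geo_series_matrix(path) -> pd.DataFrame:
    """Expression table block of a GEO series-matrix file.

    Only the rows between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` are read; metadata lines are ignored.
    """
    lines = []
    inside = False
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.lower().startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if s.lower().startswith("!series_matrix_table_end"):
                break
            if inside and s:
                lines.append(line.rstrip("\n"))
    if not lines:
        raise ValueError(f"no series-matrix table block found in {path}")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines)), sep="\t", index_col=0)
    df.index.name = "probe"
    df.index = df.index.map(lambda x: str(x).strip('"'))
    df.columns = [str(c).strip('"') for c in df.columns]
    return df


# ----------------------------------------------------------------- DE calls


def condition_slug(condition: Condition) -> str:
    return f"{condition[0]:g}kbq_{condition[1]:g}h"


def write_de_calls(calls_by_condition, out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for cond, df in calls_by_condition.items():
        p = out_dir / f"de_{condition_slug(cond)}.tsv"
        df.to_csv(p, sep="\t")
        paths.append(p)
    return paths


def read_de_calls(de_dir) -> dict[Condition, pd.DataFrame]:
    out = {}
    for p in sorted(Path(de_dir).glob("de_*kbq_*h.tsv")):
        stem = p.stem[len("de_"):]
        act_s, t_s = stem.split("kbq_")
        cond = (float(act_s), float(t_s.rstrip("h")))
        df = pd.read_csv(p, sep="\t", index_col=0)
        df["significant"] = df["significant"].astype(bool)
        df.attrs["condition"] = cond
        out[cond] = df
    if not out:
        raise ValueError(f"no DE call tables (de_*.tsv) found in {de_dir}")
    return out


# --------------------------------------------------------------- annotation


def read_annotation_tsv(path) -> dict[str, set[str]]:
    """2-column TSV ``transcript  go_id`` (header optional)."""
    with open(path) as fh:
        first = fh.readline()
    # headerless if the first line's second field already is a GO id
    fields = first.rstrip("\n").split("\t")
    header = None if len(fields) >= 2 and fields[1].startswith("GO:") else 0
    df = pd.read_csv(path, sep="\t", header=header)
    out: dict[str, set[str]] = {}
    for t, go in df.iloc[:, :2].itertuples(index=False):
        out.setdefault(str(t), set()).add(str(go))
    return out


def read_gaf(path) -> dict[str, set[str]]:
    """GAF 2.x subset reader: object id (column 2) and GO id (column 5)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                continue
            out.setdefault(fields[1], set()).add(fields[4])
    return out


def read_category_map_tsv(path) -> dict[str, tuple[str, str]]:
    """Category map TSV ``go_id  category  subcategory``."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r[0]): (str(r[1]), str(r[2]))
        for r in df.iloc[:, :3].itertuples(index=False)
    }


def read_annotation(annotation_path, category_map_path=None, gaf=False) -> AnnotationMap:
    tt = read_gaf(annotation_path) if gaf else read_annotation_tsv(annotation_path)
    cat = read_category_map_tsv(category_map_path) if category_map_path else {}
    return AnnotationMap(transcript_terms=tt, term_category=cat)


def write_annotation_tsv(amap: AnnotationMap, annotation_path, category_map_path) -> None:
    rows = [
        {"transcript": t, "go_id": go}
        for t, gos in sorted(amap.transcript_terms.items())
        for go in sorted(gos)
    ]
    pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)
    cat_rows = [
        {"go_id": go, "category": c, "subcategory": s}
        for go, (c, s) in sorted(amap.term_category.items())
    ]
    pd.DataFrame(cat_rows).to_csv(category_map_path, sep="\t", index=False)
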