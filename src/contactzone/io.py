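"""Readers and writers: STRUCTURE genotype text, FASTA, TSV, GeoJSON.

Coordinates are planar metres throughout (UTM-like grid values consumed
as-is); no geodesy. The STRUCTURE dialect is the two-row-per-individual
layout with leading columns id, site, easting, northing followed by one
allele per locus per row; the leading columns are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import MISSING, GenotypeTable, HaplotypeAlignment
from .landscape import Landscape


@dataclass
class StructureDialect:
    """Column layout of a STRUCTURE genotype file.

    ``extra_columns`` names the per-individual columns between the id and
    the loci; coordinates are picked out of them by name.
    """

    extra_columns: tuple[str, ...] = ("site", "easting", "northing")
    missing_code: int = MISSING


def read_structure_genotypes(path, dialect: StructureDialect | None = None,
                             loci: list[str] | None = None) -> GenotypeTable:
    """Parse a two-row-per-individual STRUCTURE microsatellite file."""
    dialect = dialect or StructureDialect()
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0]
    n_meta = 1 + len(dialect.extra_columns)
    if loci is None:
        loci = header[n_meta:] if len(header) > n_meta else header
        body = lines[1:]
    else:
        body = lines
    n_loci = len(loci)
    if len(body) % 2 != 0:
        raise ValueError(f"{path}: odd number of data rows ({len(body)})")
    ids, meta, alleles = [], [], []
    for i in range(0, len(body), 2):
        r1, r2 = body[i], body[i + 1]
        for j, row in ((i, r1), (i + 1, r2)):
            if len(row) != n_meta + n_loci:
                raise ValueError(
                    f"{path}: line {j + 2}: expected {n_meta + n_loci} fields, "
                    f"got {len(row)}")
        if r1[:n_meta] != r2[:n_meta]:
            raise ValueError(f"{path}: line {i + 2}: the two rows of an "
                             "individual disagree in their leading columns")
        ids.append(r1[0])
        meta.append(r1[1:n_meta])
        a = np.array([[int(v) for v in r1[n_meta:]],
                      [int(v) for v in r2[n_meta:]]]).T  # (n_loci, 2)
        a[a == dialect.missing_code] = MISSING
        alleles.append(a)
    inds = pd.DataFrame(meta, columns=list(dialect.extra_columns), index=ids)
    inds.index.name = "individual"
    for col in ("easting", "northing"):
        if col in inds.columns:
            inds[col] = inds[col].astype(float)
    arr = np.stack(alleles)
    half = (arr == MISSING)[:, :, 0] != (arr == MISSING)[:, :, 1]
    if half.any():
        i, l = np.argwhere(half)[0]
        raise ValueError(f"{path}: individual {ids[i]} locus {loci[l]}: "
                         "half-missing genotype")
    return GenotypeTable(individuals=inds, alleles=arr, loci=list(loci))


def write_structure_genotypes(gt: GenotypeTable, path,
                              dialect: StructureDialect | None = None) -> None:
    dialect = dialect or StructureDialect()
    cols = list(dialect.extra_columns)
    with open(path, "w") as fh:
        fh.write("\t".join(["individual"] + cols + gt.loci) + "\n")
        for i, (ind, row) in enumerate(gt.individuals.iterrows()):
            meta = [str(ind)] + [str(row[c]) for c in cols]
            for copy in (0, 1):
                vals = gt.alleles[i, :, copy].copy()
                vals[vals == gt.missing] = dialect.missing_code
                fh.write("\t".join(meta + [str(v) for v in vals]) + "\n")


def read_fasta(path) -> HaplotypeAlignment:
    """Read aligned sequences; carrier counts parsed from ``count=N`` in the
    description when present, else 1. Sequences are upper-cased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sequence ids")
    counts = []
    for r in records:
        n = 1
        for tok in r.description.split():
            if tok.startswith("count="):
                n = int(tok.split("=", 1)[1])
        counts.append(n)
    return HaplotypeAlignment(ids=ids, seqs=[str(r.seq) for r in records],
                              counts=np.array(counts))


def write_fasta(aln: HaplotypeAlignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description=f"count={int(n)}")
        for i, s, n in zip(aln.ids, aln.seqs, aln.counts)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_landscape_geojson(path) -> Landscape:
    """Load a landscape from GeoJSON (LineString ridgelines, extent bbox)."""
    with open(path) as fh:
        gj = json.load(fh)
    extent = tuple(gj.get("bbox"))
    ridges, labels = [], []
    for feat in gj["features"]:
        geom = feat["geometry"]
        if geom["type"] == "LineString" and feat["properties"].get("role") == "ridgeline":
            ridges.append(np.asarray(geom["coordinates"], dtype=float))
            labels.append(feat["properties"].get("label"))
    order = np.argsort([r[:, 1].mean() for r in ridges])
    ridges = [ridges[i] for i in order]
    labels = [labels[i] for i in order]
    if any(lb is None for lb in labels):
        labels = None
    return Landscape(extent=extent, ridgelines=ridges, ridge_labels=labels)


def write_landscape_geojson(landscape: Landscape, path) -> None:
    feats = []
    for lab, r in zip(landscape.ridge_labels, landscape.ridgelines):
        feats.append({
            "type": "Feature",
            "properties": {"role": "ridgeline", "label": lab},
            "geometry": {"type": "LineString",
                         "coordinates": [[float(x), float(y)] for x, y in r]},
        })
    for lab, poly in zip(landscape.catchment_labels,
                         landscape.catchment_polygons()):
        feats.append({
            "type": "Feature",
            "properties": {"role": "catchment", "label": lab},
            "geometry": {"type": "Polygon",
                         "coordinates": [[[float(x), float(y)]
                                          for x, y in poly.exterior.coords]]},
        })
    gj = {"type": "FeatureCollection", "bbox": list(landscape.extent),
          "features": feats}
    with open(path, "w") as fh:
        json.dump(gj, fh, indent=1)


def write_results_tsv(records, path, float_format: str = "%.6g") -> None:
    """Write records (DataFrame or list of dicts) as a TSV with a header."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_results_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
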