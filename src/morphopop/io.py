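"""Readers and writers for the pipeline's plain-text formats.

TPS landmark files (LM=/IMAGE=/ID=/SCALE= records) with an NTS-style
"sliders" sidecar of predecessor/landmark/successor triplets; genotype CSV
(rows = loci with a tag_id column, columns = individuals, values 0/1/2/NA);
a minimal VCF reader (GT field only); popmap TSV; FASTA via Biopython; and a
key=value truth sidecar for simulated datasets.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .morpho import LandmarkConfiguration
from .popgen import GenotypeMatrix, PopulationMap
from .simulate import SimTruth

__all__ = [
    "read_tps", "write_tps", "read_sliders", "write_sliders",
    "read_genotypes", "write_genotype_csv",
    "read_popmap", "write_popmap",
    "read_fasta", "write_fasta",
    "read_truth", "write_truth",
]


# ---------------------------------------------------------------------------
# TPS landmarks


def read_tps(path: str | Path, sliders: str | Path | None = None) -> list[LandmarkConfiguration]:
    """Parse a TPS file into landmark configurations.

    SCALE records multiply raw coordinates; a sliders sidecar (triplets of
    predecessor/landmark/successor indices, 0-based) assigns sliding roles.
    """
    roles_map = read_sliders(sliders) if sliders is not None else None
    configs: list[LandmarkConfiguration] = []
    lm_expected: int | None = None
    coords: list[tuple[float, float]] = []
    meta: dict[str, str] = {}

    def flush(lineno: int) -> None:
        nonlocal lm_expected, coords, meta
        if lm_expected is None:
            return
        if len(coords) != lm_expected:
            raise ValueError(
                f"line {lineno}: LM={lm_expected} but {len(coords)} coordinate lines")
        arr = np.array(coords, dtype=float)
        scale = float(meta.get("SCALE", 1.0))
        arr = arr * scale
        k = arr.shape[0]
        roles = None
        if roles_map is not None:
            roles = tuple(roles_map.get(i, "fixed") for i in range(k))
        configs.append(LandmarkConfiguration(
            specimen_id=meta.get("ID", meta.get("IMAGE", f"specimen{len(configs)+1}")),
            coords=arr, roles=roles))
        lm_expected, coords, meta = None, [], {}

    path = Path(path)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        if key.upper() == "LM" and _:
            flush(lineno)
            lm_expected = int(val)
        elif key.upper() in ("IMAGE", "ID", "SCALE") and _:
            meta[key.upper()] = val
        else:
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'x y', got {line!r}")
            coords.append((float(parts[0]), float(parts[1])))
    flush(lineno if configs or lm_expected is not None else 0)
    return configs


def write_tps(path: str | Path, configs: list[LandmarkConfiguration]) -> None:
    lines = []
    for c in configs:
        lines.append(f"LM={c.k}")
        for x, y in c.coords:
            lines.append(f"{x:.10g} {y:.10g}")
        lines.append(f"ID={c.specimen_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sliders(path: str | Path) -> dict[int, tuple[int, int]]:
    """Sliders sidecar: whitespace triplets predecessor landmark successor (0-based)."""
    out: dict[int, tuple[int, int]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        pred, lm, succ = (int(x) for x in line.split())
        out[lm] = (pred, succ)
    return out


def write_sliders(path: str | Path, roles) -> None:
    lines = ["# predecessor landmark successor (0-based)"]
    for i, r in enumerate(roles):
        if r != "fixed":
            lines.append(f"{r[0]} {i} {r[1]}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# genotypes


def write_genotype_csv(path: str | Path, g: GenotypeMatrix) -> None:
    """Rows = loci (locus, tag_id, then one column per individual); NA missing."""
    df = pd.DataFrame(g.genotypes.T, index=g.loci, columns=g.individuals)
    df.insert(0, "tag_id", g.tags)
    df.index.name = "locus"
    df.to_csv(path, na_rep="NA", float_format="%.0f")


def read_genotype_csv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0, dtype={"tag_id": str})
    if "tag_id" not in df.columns:
        raise ValueError("genotype CSV must have a 'tag_id' column")
    tags = df["tag_id"].tolist()
    vals = df.drop(columns="tag_id")
    arr = vals.to_numpy(dtype=float).T
    bad = ~np.isnan(arr) & ~np.isin(arr, (0.0, 1.0, 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype {arr[i, j]!r} for individual "
            f"{vals.columns[i]!r} at locus {vals.index[j]!r}")
    return GenotypeMatrix(arr, list(vals.columns), list(vals.index), tags)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Minimal VCF reader: biallelic SNPs, GT subfield only, ./. = missing.

    Multi-allelic records are skipped with a warning.
    """
    individuals: list[str] = []
    loci: list[str] = []
    tags: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("##") or not raw.strip():
            continue
        if raw.startswith("#CHROM"):
            individuals = raw.rstrip("\n").split("\t")[9:]
            continue
        f = raw.rstrip("\n").split("\t")
        chrom, pos, vid, ref, alt = f[0], f[1], f[2], f[3], f[4]
        if "," in alt or len(ref) != 1 or len(alt) != 1:
            n_skipped += 1
            continue
        fmt = f[8].split(":")
        try:
            gt_i = fmt.index("GT")
        except ValueError:
            raise ValueError(f"record {chrom}:{pos} has no GT field")
        row = np.empty(len(individuals))
        for i, sample in enumerate(f[9:]):
            gt = sample.split(":")[gt_i].replace("|", "/")
            alleles = gt.split("/")
            if "." in alleles:
                row[i] = np.nan
            else:
                row[i] = sum(int(a) for a in alleles)
        rows.append(row)
        loci.append(vid if vid != "." else f"{chrom}:{pos}")
        tags.append(chrom + ":" + pos)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} multi-allelic/non-SNP record(s)")
    if not individuals:
        raise ValueError("no #CHROM header line found")
    return GenotypeMatrix(np.array(rows).T, individuals, loci, tags)


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Dispatch on format ('csv' or 'vcf'; inferred from the suffix by default)."""
    path = Path(path)
    fmt = format or ("vcf" if path.suffix.lower() == ".vcf" else "csv")
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "csv":
        return read_genotype_csv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# popmap


def write_popmap(path: str | Path, pm: PopulationMap) -> None:
    pm.to_frame().to_csv(path, sep="\t", index=False)


def read_popmap(path: str | Path) -> PopulationMap:
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "population": str})
    if not {"individual", "population"}.issubset(df.columns):
        raise ValueError("popmap needs 'individual' and 'population' columns")
    pop_of = dict(zip(df["individual"], df["population"]))
    region_of: dict[str, str] = {}
    coords: dict[str, tuple[float, float]] = {}
    for _, r in df.iterrows():
        if "region" in df.columns and isinstance(r.get("region"), str) and r["region"]:
            region_of[r["population"]] = r["region"]
        if {"lat", "lon"}.issubset(df.columns) and np.isfinite(r.get("lat", np.nan)):
            coords[r["population"]] = (float(r["lat"]), float(r["lon"]))
    return PopulationMap(pop_of, region_of, coords)


# ---------------------------------------------------------------------------
# FASTA and truth sidecars


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_truth(path: str | Path, truth: SimTruth) -> None:
    lines = [f"{k}={getattr(truth, k)}" for k in
             ("fst_true", "sigma2_B_true", "sigma2_W_true", "n_segsites_true", "seed")]
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path: str | Path) -> SimTruth:
    kv = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            kv[k] = v
    return SimTruth(
        fst_true=float(kv["fst_true"]),
        sigma2_B_true=float(kv["sigma2_B_true"]),
        sigma2_W_true=float(kv["sigma2_W_true"]),
        n_segsites_true=int(kv["n_segsites_true"]),
        seed=int(kv["seed"]),
    )
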