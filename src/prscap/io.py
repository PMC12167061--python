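"""Readers/writers: TSV metadata, dosage matrices with JSON sidecar, BED, minimal VCF."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import CaptureTable
from .synthgeno import AnnotationSet, GenotypePanel

__all__ = [
    "write_panel",
    "read_panel",
    "write_bed",
    "read_bed",
    "write_capture_table",
    "read_capture_table",
    "write_vcf",
]


def write_panel(panel: GenotypePanel, outdir: str | Path, name: str = "panel") -> Path:
    """Write metadata TSV, dosage TSVs, and a JSON sidecar; returns the directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel.meta.to_csv(outdir / f"{name}.variants.tsv", sep="\t", index=False)
    np.savetxt(outdir / f"{name}.true_dosage.tsv", panel.true_dosage, fmt="%d", delimiter="\t")
    if panel.imputed_dosage is not None:
        np.savetxt(
            outdir / f"{name}.imputed_dosage.tsv",
            panel.imputed_dosage,
            fmt="%.6g",
            delimiter="\t",
        )
    sidecar = {
        "n_individuals": panel.n_individuals,
        "m_variants": panel.m_variants,
        "seed": panel.seed,
        "has_imputed": panel.imputed_dosage is not None,
    }
    (outdir / f"{name}.json").write_text(json.dumps(sidecar, indent=2))
    return outdir


def read_panel(outdir: str | Path, name: str = "panel") -> GenotypePanel:
    outdir = Path(outdir)
    meta = pd.read_csv(outdir / f"{name}.variants.tsv", sep="\t")
    sidecar = json.loads((outdir / f"{name}.json").read_text())
    true_dosage = np.loadtxt(outdir / f"{name}.true_dosage.tsv", dtype=np.int8, ndmin=2)
    imputed = None
    if sidecar.get("has_imputed"):
        imputed = np.loadtxt(outdir / f"{name}.imputed_dosage.tsv", ndmin=2)
    return GenotypePanel(meta=meta, true_dosage=true_dosage, imputed_dosage=imputed, seed=sidecar.get("seed"))


def write_bed(annotations: AnnotationSet, outdir: str | Path) -> list[Path]:
    """One BED file per track; internal 1-based inclusive -> 0-based half-open."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, ivals in annotations.tracks.items():
        path = outdir / f"{name}.bed"
        with open(path, "w") as fh:
            for start, end in np.asarray(ivals, dtype=np.int64):
                fh.write(f"{annotations.chrom}\t{start - 1}\t{end}\t{name}\n")
        paths.append(path)
    return paths


def read_bed(paths, chrom: str = "22", span: tuple[int, int] | None = None) -> AnnotationSet:
    """Read BED files (0-based half-open) into 1-based inclusive tracks.

    The track name is the file stem; the category is the stem up to the last
    underscore (matching the generator's naming), else the stem itself.
    """
    tracks: dict[str, np.ndarray] = {}
    categories: dict[str, str] = {}
    for path in map(Path, paths):
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
        )
        df = df[df["chrom"].astype(str) == chrom]
        name = path.stem
        tracks[name] = np.column_stack(
            [df["start"].to_numpy(np.int64) + 1, df["end"].to_numpy(np.int64)]
        )
        categories[name] = name.rsplit("_", 1)[0] if "_" in name else name
    return AnnotationSet(tracks, categories, chrom=chrom, span=span)


def write_capture_table(capture: CaptureTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    capture.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_capture_table(path: str | Path) -> CaptureTable:
    df = pd.read_csv(path, sep="\t")
    return CaptureTable(
        r2_imput=df["r2_imput"].to_numpy(float),
        rho2=df["rho2"].to_numpy(float),
        maf=df["maf"].to_numpy(float),
        is_genotyped=df["is_genotyped"].to_numpy(bool),
    )


def write_vcf(panel: GenotypePanel, path: str | Path) -> Path:
    """Minimal GT-only VCF export of the true dosages."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = panel.n_individuals
    samples = "\t".join(f"S{i:05d}" for i in range(n))
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        chrom = panel.meta["chrom"].astype(str).to_numpy()
        pos = panel.pos
        for j in range(panel.m_variants):
            gts = "\t".join(gt_map[int(d)] for d in panel.true_dosage[:, j])
            fh.write(f"{chrom[j]}\t{pos[j]}\tvar{j}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
    return path
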