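"""File formats and reproducibility plumbing.

Genotypes travel either as a phased VCF 4.2 subset or as a plain
tab-separated 0/1/2 matrix (rows = individuals, columns = markers).
Positions are genetic-map coordinates: the VCF POS column encodes
``round(cM * 1e4) + 1`` and the exact cM value is kept in ``INFO/CM``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stage_seed
from .breeding import Population
from .genmap import GeneticMap

__all__ = [
    "write_vcf",
    "write_genotype_matrix",
    "read_genotypes",
    "write_phenotypes",
    "read_phenotypes",
    "intersect_markers",
    "RunLog",
    "run_logger",
    "config_hash",
]


def write_vcf(path, gmap: GeneticMap, population: Population) -> None:
    """Write phased, diploid genotypes as a minimal VCF 4.2 file."""
    ids = population.ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic map position (cM)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for cid, length in zip(gmap.chrom_ids, gmap.chrom_lengths):
            fh.write(f"##contig=<ID={cid},length={int(length * 1e4) + 2}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        haps = np.stack([ind.haplotypes for ind in population])  # (n, 2, m)
        for j in range(gmap.n_markers):
            chrom = gmap.chrom_ids[gmap.marker_chrom[j]]
            pos = int(round(gmap.positions_cm[j] * 1e4)) + 1
            gts = "\t".join(f"{haps[i, 0, j]}|{haps[i, 1, j]}" for i in range(len(ids)))
            fh.write(
                f"{chrom}\t{pos}\t{gmap.marker_ids[j]}\tA\tT\t.\tPASS\t"
                f"CM={gmap.positions_cm[j]:.6f}\tGT\t{gts}\n"
            )


def write_genotype_matrix(path, marker_ids, ids, genotypes: np.ndarray) -> None:
    """Plain TSV: one row per individual, one 0/1/2 column per marker."""
    pd.DataFrame(np.asarray(genotypes), index=list(ids), columns=list(marker_ids)).to_csv(
        path, sep="\t", index_label="id"
    )


def _prescan_vcf(path) -> None:
    """Structural scan so malformed lines fail with a line number."""
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                n_cols = len(parts)
                if n_cols < 10:
                    raise ValueError(f"malformed VCF header at line {lineno}: no samples")
                continue
            if n_cols is None:
                raise ValueError(f"malformed VCF: data before header at line {lineno}")
            if len(parts) != n_cols:
                raise ValueError(
                    f"malformed VCF line {lineno}: {len(parts)} columns, expected {n_cols}"
                )
            for sample in parts[9:]:
                gt = sample.split(":")[0]
                alleles = gt.replace("|", "/").split("/")
                if len(alleles) != 2:
                    raise ValueError(f"mixed or non-diploid genotype at line {lineno}: {gt!r}")
                for a in alleles:
                    if a not in ("0", "1", "."):
                        raise ValueError(f"unknown allele at line {lineno}: {gt!r}")


def read_genotypes(path, fmt: str = "vcf"):
    """Read genotypes as (genotype matrix, individual ids, marker table).

    ``fmt='vcf'`` additionally returns phased haplotypes in the marker
    table's attrs; ``fmt='matrix'`` reads the TSV written by
    :func:`write_genotype_matrix`.
    """
    if fmt == "matrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        markers = pd.DataFrame({"marker_id": df.columns})
        return df.to_numpy(dtype=np.int8), list(df.index), markers
    if fmt != "vcf":
        raise ValueError("fmt must be 'vcf' or 'matrix'")
    _prescan_vcf(path)
    chroms, poss, mids, cms, rows_a, rows_b = [], [], [], [], [], []
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                ids = parts[9:]
                continue
            chroms.append(parts[0])
            poss.append(int(parts[1]))
            mids.append(parts[2])
            cm = np.nan
            for kv in parts[7].split(";"):
                if kv.startswith("CM="):
                    cm = float(kv[3:])
            cms.append(cm)
            a = np.empty(len(ids), dtype=np.int8)
            b = np.empty(len(ids), dtype=np.int8)
            for i, sample in enumerate(parts[9:]):
                gt = sample.split(":")[0]
                al = gt.replace("|", "/").split("/")
                a[i] = -1 if al[0] == "." else int(al[0])
                b[i] = -1 if al[1] == "." else int(al[1])
            rows_a.append(a)
            rows_b.append(b)
    hap_a = np.stack(rows_a).T  # (n, m)
    hap_b = np.stack(rows_b).T
    geno = np.where((hap_a < 0) | (hap_b < 0), -1, hap_a + hap_b).astype(np.int8)
    markers = pd.DataFrame(
        {"marker_id": mids, "chrom": chroms, "pos": poss, "cm": cms}
    )
    markers.attrs["haplotypes"] = (hap_a, hap_b)
    # order by map position within chromosome
    order = markers.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    markers = markers.loc[order].reset_index(drop=True)
    markers.attrs["haplotypes"] = (hap_a[:, order], hap_b[:, order])
    return geno[:, order], ids, markers


def write_phenotypes(path, records: pd.DataFrame) -> None:
    records.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"genotype", "population", "environment", "replication", "block"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def intersect_markers(set_a: list[str], set_b: list[str]) -> tuple[list[str], float]:
    """Ordered intersection plus overlap fraction relative to the smaller set."""
    b = set(set_b)
    common = [m for m in set_a if m in b]
    smaller = min(len(set_a), len(set_b))
    fraction = len(common) / smaller if smaller else 0.0
    if not common:
        import warnings

        warnings.warn("marker sets are disjoint", stacklevel=2)
    return common, fraction


# --------------------------------------------------------------- run log


def config_hash(config) -> str:
    from dataclasses import asdict, is_dataclass

    payload = asdict(config) if is_dataclass(config) else dict(config)
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


@dataclass
class RunLog:
    """Structured provenance: config hash, per-stage sub-seeds and timings."""

    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    _t0: float = field(default_factory=time.perf_counter, repr=False)

    def record(self, stage: str, **extra) -> None:
        self.stages.append(
            {
                "stage": stage,
                "sub_seed": stage_seed(self.seed, stage),
                "elapsed_s": round(time.perf_counter() - self._t0, 3),
                **extra,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed, "stages": self.stages},
            indent=2,
        )


def run_logger(config, seed: int) -> RunLog:
    return RunLog(config_hash=config_hash(config), seed=seed)
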