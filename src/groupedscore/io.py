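"""Readers and writers for phenotype, covariate, genotype and gene-set data.

Supported genotype sources: delimited TSV (samples x variants), binary
PLINK BED/BIM/FAM triplets, and VCF with per-genotype dosage (``DS``) or
hard calls (``GT``, additive coding).  Sample alignment across files is
always by sample ID, never positional.  Missing dosages (TSV ``NA``/empty,
VCF ``.``, the native PLINK missing code) are normalised to NaN.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_phenotype",
    "write_phenotype",
    "read_covariates",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_plink",
    "read_gene_sets",
    "write_results",
    "write_qq",
    "align_genotypes",
    "hwe_exact_pvalue",
    "variant_qc_mask",
]


# ---------------------------------------------------------------------------
# phenotype / covariates
# ---------------------------------------------------------------------------

def read_phenotype(path) -> Tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Read a grouped-outcome table with columns sample_id, interval, event.

    Returns ``(k, delta, sample_ids, r)`` with ``r`` inferred as the maximum
    interval index.  Malformed records raise with the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "interval", "event"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: header must start with {required}, got {list(df.columns[:3])}")
    k = np.empty(len(df), dtype=np.int64)
    delta = np.empty(len(df), dtype=np.int64)
    for i, (kv, ev) in enumerate(zip(df["interval"], df["event"])):
        line = i + 2  # header is line 1
        try:
            kf = float(kv)
            if not kf.is_integer() or kf < 1:
                raise ValueError
            k[i] = int(kf)
        except (TypeError, ValueError):
            raise ValueError(f"{path}: line {line}: non-integer interval {kv!r}") from None
        if ev not in ("0", "1"):
            raise ValueError(f"{path}: line {line}: event must be 0 or 1, got {ev!r}")
        delta[i] = int(ev)
    ids = df["sample_id"].to_numpy()
    dup = pd.Series(ids).duplicated()
    if dup.any():
        lines = [str(i + 2) for i in np.flatnonzero(dup.to_numpy())]
        raise ValueError(f"{path}: duplicate sample ids at lines {', '.join(lines)}")
    return k, delta, ids, int(k.max())


def write_phenotype(path, k, delta, sample_ids) -> None:
    pd.DataFrame({"sample_id": sample_ids, "interval": k, "event": delta}).to_csv(
        path, sep="\t", index=False
    )


def read_covariates(path, columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Covariate table: first column sample_id, remaining columns numeric."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be sample_id")
    df = df.set_index("sample_id")
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: covariate columns not found: {missing}")
        df = df[list(columns)]
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric covariate value ({exc})") from None
    return df


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, fmt: str = "tsv"):
    """Dispatch on format; returns ``(G, variant_ids, sample_ids)``.

    ``G`` is an n-by-m float matrix of dosages in [0, 2] with NaN for
    missing entries.
    """
    if fmt == "tsv":
        return _read_genotypes_tsv(path)
    if fmt == "vcf":
        return _read_genotypes_vcf(path)
    if fmt == "bed":
        return _read_genotypes_bed(path)
    raise ValueError(f"unknown genotype format {fmt!r} (expected tsv, vcf or bed)")


def _read_genotypes_tsv(path):
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be sample_id")
    ids = df["sample_id"].astype(str).to_numpy()
    G = df.drop(columns="sample_id").to_numpy(dtype=float)
    if np.nanmin(G, initial=0.0) < 0 or np.nanmax(G, initial=0.0) > 2:
        raise ValueError(f"{path}: dosages must lie in [0, 2]")
    return G, df.columns[1:].to_numpy(), ids


def write_genotypes_tsv(path, G, variant_ids, sample_ids) -> None:
    df = pd.DataFrame(G, columns=variant_ids)
    df.insert(0, "sample_id", sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def _read_genotypes_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = np.asarray(vcf.samples)
    cols: List[np.ndarray] = []
    ids: List[str] = []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic record %s:%s", var.CHROM, var.POS)
            continue
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where((col < 0) | (col > 2), np.nan, col)
        else:
            gt = np.asarray(var.genotypes, dtype=object)
            col = np.empty(len(sample_ids))
            for i, g in enumerate(gt):
                a = [al for al in g[:-1]]
                if any(al is None or al < 0 for al in a):
                    col[i] = np.nan
                else:
                    col[i] = float(sum(1 for al in a if al == 1))
        cols.append(col)
        ids.append(vid)
    G = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    return G, np.asarray(ids), sample_ids


# PLINK 1.9 binary format: 3 magic bytes then, variant-major, 2 bits per
# sample: 00 hom A1, 01 missing, 10 het, 11 hom A2.  Dosage counts A1.
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
_BED_CODE_TO_DOSAGE = {0: 2.0, 1: np.nan, 2: 1.0, 3: 0.0}


def _read_genotypes_bed(path):
    path = Path(path)
    stem = path.with_suffix("")
    bim = pd.read_csv(
        stem.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "vid", "cm", "pos", "a1", "a2"], dtype=str,
    )
    fam = pd.read_csv(
        stem.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
    )
    sample_ids = fam["iid"].to_numpy()
    n, m = len(fam), len(bim)
    raw = stem.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{path}: not a variant-major PLINK BED file")
    stride = math.ceil(n / 4)
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != stride * m:
        raise ValueError(f"{path}: BED payload size does not match BIM/FAM dimensions")
    body = body.reshape(m, stride)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11  # (m, stride, 4)
    codes = codes.reshape(m, stride * 4)[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    G = lut[codes].T  # (n, m)
    return G, bim["vid"].to_numpy(), sample_ids


def write_plink(prefix, G, variant_ids, sample_ids) -> None:
    """Write a BED/BIM/FAM triplet (hard calls only; NaN becomes missing)."""
    prefix = Path(prefix)
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j, vid in enumerate(variant_ids):
            fh.write(f"1 {vid} 0 {j + 1} A B\n")
    code = np.full(G.shape, 1, dtype=np.uint8)  # missing
    code[G == 2] = 0
    code[G == 1] = 2
    code[G == 0] = 3
    stride = math.ceil(n / 4)
    padded = np.ones((m, stride * 4), dtype=np.uint8)  # pad with missing
    padded[:, :n] = code.T
    packed = np.zeros((m, stride), dtype=np.uint8)
    for s in range(4):
        packed |= padded[:, s::4] << (2 * s)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def align_genotypes(
    pheno_ids: np.ndarray,
    G: np.ndarray,
    geno_ids: np.ndarray,
    allow_missing: bool = False,
):
    """Reorder genotype rows to the phenotype sample order by ID join.

    Genotype-only samples are dropped (logged); phenotype samples with no
    genotype row are an error unless ``allow_missing`` (then all-NaN rows).
    """
    pheno_ids = np.asarray(pheno_ids)
    geno_ids = np.asarray(geno_ids)
    pos = {s: i for i, s in enumerate(geno_ids)}
    extra = [s for s in geno_ids if s not in set(pheno_ids)]
    if extra:
        logger.info("dropping %d genotype samples absent from phenotype", len(extra))
    missing = [s for s in pheno_ids if s not in pos]
    if missing and not allow_missing:
        raise ValueError(
            f"{len(missing)} phenotype samples lack genotypes (e.g. {missing[:5]}); "
            "pass allow_missing to keep them with all-missing dosages"
        )
    out = np.full((len(pheno_ids), G.shape[1]), np.nan)
    for i, s in enumerate(pheno_ids):
        if s in pos:
            out[i] = G[pos[s]]
    return out


# ---------------------------------------------------------------------------
# gene sets / results
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> Dict[str, List[str]]:
    """Two-column table ``set_id <tab> variant_id`` -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["set_id", "variant_id"]:
        raise ValueError(f"{path}: header must be set_id, variant_id")
    sets: Dict[str, List[str]] = {}
    for sid, vid in zip(df["set_id"], df["variant_id"]):
        sets.setdefault(sid, []).append(vid)
    return sets


def write_results(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def write_qq(pvalues: np.ndarray, path) -> None:
    """Plain-text QQ export: expected vs observed -log10 p, sorted."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    p = p[~np.isnan(p)]
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(p)
    pd.DataFrame({"expected_neglog10p": expected[::-1], "observed_neglog10p": observed[::-1]}).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


# ---------------------------------------------------------------------------
# variant QC
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy–Weinberg test p-value (two-sided, no mid-p correction).

    Uses the stable recurrence over heterozygote counts conditional on the
    allele counts; the p-value sums the probabilities of all heterozygote
    counts no more likely than the observed one.
    """
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    # possible het counts share the parity of the rare-allele count
    het_values = list(range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2))
    n_common = 2 * n - n_rare
    # ratio recurrence in log space, anchored at the middle het count:
    # P(h+2)/P(h) = 4 hom_r hom_c / ((h+2)(h+1))
    mid = het_values[len(het_values) // 2]
    logp = {mid: 0.0}
    h = mid
    while h - 2 >= het_values[0]:
        hom_r = (n_rare - h) // 2
        hom_c = (n_common - h) // 2
        logp[h - 2] = logp[h] + math.log(h * (h - 1)) - math.log(4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = mid
    while h + 2 <= het_values[-1]:
        hom_r = (n_rare - h) // 2
        hom_c = (n_common - h) // 2
        logp[h + 2] = logp[h] + math.log(4.0 * hom_r * hom_c) - math.log((h + 2) * (h + 1))
        h += 2
    lmax = max(logp.values())
    total = sum(math.exp(v - lmax) for v in logp.values())
    probs = {k: math.exp(v - lmax) / total for k, v in logp.items()}
    p_obs = probs[n_het]
    return float(min(1.0, sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12))))


def variant_qc_mask(
    G: np.ndarray,
    maf_min: Optional[float] = None,
    callrate_min: Optional[float] = None,
    hwe_min: Optional[float] = None,
):
    """Boolean keep-mask for optional pre-scan variant filters.

    All filters default to off.  The HWE test needs hard genotype calls, so
    dosages are rounded to the nearest integer for the purpose of the test.
    Returns ``(mask, report)`` where the report counts exclusions per filter.
    """
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    keep = np.ones(m, dtype=bool)
    report = {}
    called = ~np.isnan(G)
    if callrate_min is not None:
        cr = called.mean(axis=0)
        bad = cr < callrate_min
        report["callrate"] = int(bad.sum())
        keep &= ~bad
    if maf_min is not None:
        with np.errstate(invalid="ignore"):
            f = np.nanmean(G, axis=0) / 2.0
        maf = np.minimum(f, 1 - f)
        bad = ~(maf >= maf_min)
        report["maf"] = int(bad.sum())
        keep &= ~bad
    if hwe_min is not None:
        bad = np.zeros(m, dtype=bool)
        for j in range(m):
            g = np.rint(G[called[:, j], j]).astype(int)
            counts = np.bincount(np.clip(g, 0, 2), minlength=3)
            p = hwe_exact_pvalue(int(counts[1]), int(counts[0]), int(counts[2]))
            bad[j] = p < hwe_min
        report["hwe"] = int(bad.sum())
        keep &= ~bad
    return keep, report
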