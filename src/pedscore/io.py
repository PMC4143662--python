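"""Readers and writers for the study's on-disk formats.

Genotypes travel as PLINK 1 binary (BED/BIM/FAM, variant-major); traits
and all analysis outputs are plain TSV. Writers are deterministic:
stable column order, fixed float formatting (%.10g) and POSIX newlines,
so identical runs produce byte-identical files.

The BED codec implements the public 2-bit encoding directly: magic
bytes 0x6c 0x1b, mode byte 0x01 (variant-major), then per SNP
ceil(N/4) bytes with two bits per sample — 00 homozygous A1,
01 missing, 10 heterozygous, 11 homozygous A2. Dosages count the A1
(reference) allele, so 2 -> 00, 1 -> 10, 0 -> 11.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import MISSING, GenotypeMatrix, Pedigree, TraitPanel

__all__ = [
    "read_plink",
    "write_plink",
    "read_traits",
    "write_traits",
    "write_truth",
    "write_kinship",
    "write_scan",
    "write_blup",
    "write_snpset",
    "write_scores",
    "write_summary",
]

_MAGIC = b"\x6c\x1b"
_VARIANT_MAJOR = b"\x01"
# dosage (count of A1) -> 2-bit code, and back; 01 is the missing code
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def _ext(prefix: "str | Path", ext: str) -> "Path":
    prefix = Path(prefix)
    return prefix.parent / f"{prefix.name}.{ext}"


def write_plink(prefix: str | Path, pedigree: Pedigree, genotypes: GenotypeMatrix) -> None:
    """Write .bed/.bim/.fam at ``prefix`` (variant-major BED)."""
    prefix = Path(prefix)
    if genotypes.sample_ids != pedigree.ids:
        raise ValueError("genotype sample order must match pedigree order")
    n, j = genotypes.n, genotypes.n_snps

    fam = pedigree.table.assign(phenotype=-9)
    fam.loc[:, ["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"]].to_csv(
        _ext(prefix, "fam"), sep=" ", header=False, index=False, lineterminator="\n"
    )

    bim = genotypes.snp_map.assign(cm=0)
    bim.loc[:, ["chromosome", "snp_id", "cm", "bp_position", "ref_allele", "alt_allele"]].to_csv(
        _ext(prefix, "bim"), sep="\t", header=False, index=False, lineterminator="\n"
    )

    lut = np.zeros(256, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        lut[dosage % 256] = code
    codes = lut[genotypes.dosages.T.view(np.uint8)]  # J x N
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros((j, pad), dtype=np.uint8)], axis=1)
    codes = codes.reshape(j, -1, 4)
    packed = (
        codes[:, :, 0] | (codes[:, :, 1] << 2) | (codes[:, :, 2] << 4) | (codes[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(_ext(prefix, "bed"), "wb") as fh:
        fh.write(_MAGIC + _VARIANT_MAJOR)
        fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> tuple[Pedigree, GenotypeMatrix]:
    """Read .bed/.bim/.fam at ``prefix``; round-trips :func:`write_plink`."""
    prefix = Path(prefix)
    fam_path, bim_path, bed_path = (
        _ext(prefix, "fam"),
        _ext(prefix, "bim"),
        _ext(prefix, "bed"),
    )
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(f"missing PLINK file {p}")

    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"],
        dtype={"family_id": str, "individual_id": str, "father_id": str, "mother_id": str},
    )
    pedigree = Pedigree(
        fam.loc[:, ["individual_id", "family_id", "father_id", "mother_id", "sex"]]
    )
    bim = pd.read_csv(
        bim_path,
        sep="\t",
        header=None,
        names=["chromosome", "snp_id", "cm", "bp_position", "ref_allele", "alt_allele"],
        dtype={"snp_id": str, "ref_allele": str, "alt_allele": str},
    )
    n, j = len(fam), len(bim)

    raw = bed_path.read_bytes()
    if raw[:2] != _MAGIC:
        raise ValueError(f"{bed_path}: bad magic bytes {raw[:2]!r}, expected {_MAGIC!r}")
    if raw[2:3] != _VARIANT_MAJOR:
        raise ValueError(f"{bed_path}: unsupported mode byte {raw[2:3]!r} (sample-major?)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + j * bytes_per_snp
    if len(raw) != expected:
        raise ValueError(
            f"{bed_path}: expected {expected} bytes for {n} samples x {j} SNPs, got {len(raw)}"
        )
    packed = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(j, bytes_per_snp)
    codes = np.empty((j, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (packed >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # N x J

    snp_map = bim.loc[:, ["snp_id", "chromosome", "bp_position", "ref_allele", "alt_allele"]]
    return pedigree, GenotypeMatrix(dosages, snp_map, pedigree.ids)


# ---------------------------------------------------------------------------
# Trait panel TSV
# ---------------------------------------------------------------------------

def write_traits(path: str | Path, panel: TraitPanel) -> None:
    """Trait panel TSV: id, age, sex, rep1..repR."""
    cols = {"id": panel.individual_ids, "age": panel.age, "sex": panel.sex}
    for r in range(1, panel.n_replicates + 1):
        cols[f"rep{r}"] = panel.traits[:, r - 1]
    pd.DataFrame(cols).to_csv(
        path, sep="\t", index=False, float_format="%.10g", lineterminator="\n"
    )


def read_traits(path: str | Path, fam_ids: list[str] | None = None) -> TraitPanel:
    """Read a trait panel TSV; ids are matched (and reordered) to ``fam_ids``."""
    t = pd.read_csv(path, sep="\t", dtype={"id": str})
    for col in ("id", "age", "sex"):
        if col not in t.columns:
            raise ValueError(f"traits file missing required column {col!r}")
    rep_cols = [c for c in t.columns if c.startswith("rep")]
    if len(rep_cols) < 2:
        raise ValueError("traits file must have at least 2 replicate columns (rep1, rep2, ...)")
    if t["id"].duplicated().any():
        dup = t.loc[t["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate individual ids in traits file: {dup}")
    if fam_ids is not None:
        extra = sorted(set(t["id"]) - set(fam_ids))
        absent = sorted(set(fam_ids) - set(t["id"]))
        if extra or absent:
            raise ValueError(
                f"trait ids do not match genotype sample ids (unknown: {extra}, missing: {absent})"
            )
        t = t.set_index("id").loc[fam_ids].reset_index()
    traits = t.loc[:, rep_cols].to_numpy(dtype=float)
    if np.isnan(traits).any():
        raise ValueError("non-numeric or missing trait values")
    return TraitPanel(
        individual_ids=list(t["id"]),
        age=t["age"].to_numpy(dtype=float),
        sex=t["sex"].to_numpy(dtype=int),
        traits=traits,
        trait_kind="dbp_like",
        truth=[{"replicate": r + 1, "causal_snps": []} for r in range(traits.shape[1])],
    )


def write_truth(path: str | Path, panel: TraitPanel) -> None:
    """Generator truth sidecar: one row per replicate."""
    rows = [
        {
            "replicate": rec["replicate"],
            "major_snps": ",".join(rec.get("major_snps", [])),
            "n_weak": len(rec.get("weak_snps", [])),
            "n_polygenic": len(rec.get("polygenic_snps", [])),
            "polygenic_snps": ",".join(rec.get("polygenic_snps", [])),
        }
        for rec in panel.truth
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Analysis-output writers (all deterministic)
# ---------------------------------------------------------------------------

def _write_tsv(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def write_kinship(path: str | Path, kinship) -> None:
    """Square TSV with the id order as header and first column."""
    frame = pd.DataFrame(kinship.values, columns=kinship.id_order)
    frame.insert(0, "id", kinship.id_order)
    _write_tsv(path, frame)


def write_scan(path: str | Path, result) -> None:
    _write_tsv(path, result.table.loc[:, ["snp_id", "chromosome", "bp_position", "beta", "se", "p"]])


def write_blup(path: str | Path, fit) -> None:
    _write_tsv(path, pd.DataFrame({"snp_id": fit.included_snps, "alpha_hat": fit.alpha_hat}))


def write_snpset(path: str | Path, snp_set) -> None:
    """PLINK --score compatible 3-column TSV: snp_id, ref_allele, weight."""
    _write_tsv(path, snp_set.entries.loc[:, ["snp_id", "ref_allele", "weight"]])


def write_scores(path: str | Path, scores) -> None:
    _write_tsv(
        path,
        pd.DataFrame(
            {
                "id": scores.individual_ids,
                "ps": scores.ps,
                "n_imputed": scores.n_missing_imputed,
            }
        ),
    )


def write_summary(path: str | Path, summary) -> None:
    _write_tsv(
        path,
        summary.table.loc[:, ["strategy", "S", "alpha", "n_replicates", "n_significant", "rate"]],
    )
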