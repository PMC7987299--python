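"""Interchange formats and allele harmonization.

Containers
----------
``GwasSummary``
    One scan's per-SNP summary statistics (tab-delimited on disk with
    header ``SNP CHR BP A1 A2 Z N``; ``A1`` is the effect allele).
``GenotypePanel``
    A reference panel of diploid dosages with SNP metadata; read/written
    as PLINK-style transposed text (``.tped``/``.tfam``) or VCF v4.2.
``WeightModel`` (defined in :mod:`twaskit.weights`)
    Serialized here as a versioned tab-delimited weight file: per-gene
    metadata lines (``#GENE``) followed by one row per gene-SNP pair.

Harmonization
-------------
:func:`harmonize_alleles` aligns a GWAS scan's effect alleles to the
reference panel, flipping z signs for swapped alleles, resolving
unambiguous strand flips, and dropping strand-ambiguous (A/T, C/G) or
irreconcilable SNPs.  All coordinates are 1-based and inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GwasSummary",
    "GenotypePanel",
    "HarmonizationReport",
    "FilterReport",
    "harmonize_alleles",
    "apply_input_filters",
    "read_gwas",
    "write_gwas",
    "read_weights",
    "write_weights",
    "load_table1_fixture",
    "load_table2_fixture",
]

SCAN_LABELS = ("overall", "er_pos", "er_neg", "case_only")
GWAS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "Z", "N"]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_WEIGHT_FILE_VERSION = "twaskit-weights-v1"


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


@dataclass
class HarmonizationReport:
    n_input: int = 0
    n_kept: int = 0
    n_sign_flipped: int = 0
    n_strand_flipped: int = 0
    n_ambiguous_dropped: int = 0
    n_unmatched_dropped: int = 0
    n_irreconcilable_dropped: int = 0
    irreconcilable_snps: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    n_input: int = 0
    n_retained: int = 0
    n_failed_maf: int = 0
    n_failed_info: int = 0
    n_missing_metadata: int = 0
    missing_snps: list[str] = field(default_factory=list)


@dataclass
class GwasSummary:
    """Per-SNP summary statistics for one association scan."""

    table: pd.DataFrame
    scan_label: str = "overall"
    harmonization: HarmonizationReport | None = None
    filter_report: FilterReport | None = None

    def __post_init__(self) -> None:
        if self.scan_label not in SCAN_LABELS:
            raise ValueError(f"scan_label must be one of {SCAN_LABELS}, got {self.scan_label!r}")
        missing = [c for c in GWAS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"GWAS table missing columns: {missing}")
        t = self.table
        if t["SNP"].duplicated().any():
            raise ValueError("duplicate SNP ids within a scan")
        if (t["A1"] == t["A2"]).any():
            raise ValueError("effect and other allele identical for some SNP")
        if not np.isfinite(t["Z"].to_numpy(float)).all():
            raise ValueError("non-finite z-scores")
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_panel(
        cls, panel: "GenotypePanel", z: np.ndarray, n: int, scan_label: str
    ) -> "GwasSummary":
        t = pd.DataFrame({
            "SNP": panel.snps["snp_id"].to_numpy(),
            "CHR": panel.snps["chrom"].to_numpy(),
            "BP": panel.snps["pos"].to_numpy(),
            "A1": panel.snps["a1"].to_numpy(),
            "A2": panel.snps["a2"].to_numpy(),
            "Z": np.asarray(z, dtype=float),
            "N": int(n),
        })
        return cls(table=t, scan_label=scan_label)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def z_for(self, snp_ids: Sequence[str]) -> np.ndarray:
        s = self.table.set_index("SNP")["Z"]
        return s.loc[list(snp_ids)].to_numpy(float)


@dataclass
class GenotypePanel:
    """Reference individuals x SNPs with allele labels, positions and MAFs.

    ``snps`` columns: snp_id, chrom, pos, a1 (panel effect allele), a2,
    maf.  ``dosages`` counts copies of ``a1`` and lies in {0, 1, 2}.
    """

    individual_ids: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        n, m = self.dosages.shape
        if n != len(self.individual_ids) or m != len(self.snps):
            raise ValueError("dosage matrix shape inconsistent with ids/snps")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must lie in {0, 1, 2}")
        by_chrom = self.snps.groupby("chrom", sort=False)["pos"]
        if not by_chrom.apply(lambda p: bool(p.is_monotonic_increasing)).all():
            raise ValueError("positions must be non-decreasing within chromosome")

    @classmethod
    def from_arrays(cls, individual_ids, snp_ids, chrom, positions,
                    effect_alleles, other_alleles, maf, dosages) -> "GenotypePanel":
        m = len(snp_ids)
        chroms = [chrom] * m if isinstance(chrom, str) else list(chrom)
        snps = pd.DataFrame({
            "snp_id": list(snp_ids),
            "chrom": chroms,
            "pos": np.asarray(positions, dtype=np.int64),
            "a1": list(effect_alleles),
            "a2": list(other_alleles),
            "maf": np.asarray(maf, dtype=float),
        })
        return cls(individual_ids=list(individual_ids), snps=snps, dosages=dosages)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def dosages_for(self, snp_ids: Sequence[str]) -> np.ndarray:
        idx = pd.Index(self.snps["snp_id"])
        locs = idx.get_indexer(list(snp_ids))
        if (locs < 0).any():
            missing = [s for s, l in zip(snp_ids, locs) if l < 0]
            raise KeyError(f"SNPs absent from panel: {missing[:5]}")
        return self.dosages[:, locs]

    def standardized(self, snp_ids: Sequence[str] | None = None) -> np.ndarray:
        d = self.dosages if snp_ids is None else self.dosages_for(snp_ids)
        z = d.astype(float)
        z -= z.mean(axis=0)
        sd = z.std(axis=0)
        sd[sd == 0] = 1.0
        return z / sd

    # ------------------------------------------------------------------
    # PLINK transposed text
    # ------------------------------------------------------------------
    def write_tped(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        with open(prefix.with_suffix(".tfam"), "w") as fh:
            for iid in self.individual_ids:
                fh.write(f"{iid} {iid} 0 0 0 -9\n")
        with open(prefix.with_suffix(".tped"), "w") as fh:
            for j, snp in self.snps.iterrows():
                geno = []
                for d in self.dosages[:, j]:
                    n1 = int(d)
                    geno.append(" ".join([snp.a1] * n1 + [snp.a2] * (2 - n1)))
                fh.write(f"{snp.chrom} {snp.snp_id} 0 {snp.pos} " + " ".join(geno) + "\n")

    @classmethod
    def read_tped(cls, prefix: str | Path) -> "GenotypePanel":
        prefix = Path(prefix)
        ind_ids = [line.split()[1] for line in open(prefix.with_suffix(".tfam"))]
        rows, dosage_cols = [], []
        for line in open(prefix.with_suffix(".tped")):
            parts = line.split()
            chrom, snp_id, _, pos = parts[:4]
            alleles = parts[4:]
            pairs = [(alleles[2 * i], alleles[2 * i + 1]) for i in range(len(alleles) // 2)]
            counts: dict[str, int] = {}
            for a, b in pairs:
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
            # effect allele = minor allele (ties broken lexicographically)
            obs = sorted(counts.items(), key=lambda kv: (kv[1], kv[0]))
            a1 = obs[0][0]
            a2 = obs[-1][0] if len(obs) > 1 else ("A" if a1 != "A" else "C")
            dos = np.array([(a == a1) + (b == a1) for a, b in pairs], dtype=np.int8)
            rows.append((snp_id, chrom, int(pos), a1, a2, dos.mean() / 2.0))
            dosage_cols.append(dos)
        snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "a1", "a2", "maf"])
        return cls(individual_ids=ind_ids, snps=snps,
                   dosages=np.column_stack(dosage_cols) if dosage_cols else np.empty((len(ind_ids), 0)))

    # ------------------------------------------------------------------
    # VCF v4.2 (plain text; REF = other allele, ALT = effect allele)
    # ------------------------------------------------------------------
    def write_vcf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.individual_ids) + "\n")
            for j, snp in self.snps.iterrows():
                gts = "\t".join(
                    {0: "0/0", 1: "0/1", 2: "1/1"}[int(d)] for d in self.dosages[:, j])
                fh.write(f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.a2}\t{snp.a1}"
                         f"\t.\t.\t.\tGT\t{gts}\n")

    @classmethod
    def read_vcf(cls, path: str | Path) -> "GenotypePanel":
        try:
            from cyvcf2 import VCF
        except ImportError:  # pragma: no cover - cyvcf2 is an optional reader
            return cls._read_vcf_text(path)
        vcf = VCF(str(path))
        ind_ids = list(vcf.samples)
        rows, cols = [], []
        for var in vcf:
            alt = var.ALT[0] if var.ALT else "N"
            dos = np.array([a + b for a, b, *_ in var.genotypes], dtype=np.int8)
            rows.append((var.ID, str(var.CHROM), int(var.POS), alt, var.REF,
                         dos.mean() / 2.0))
            cols.append(dos)
        snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "a1", "a2", "maf"])
        return cls(individual_ids=ind_ids, snps=snps,
                   dosages=np.column_stack(cols) if cols else np.empty((len(ind_ids), 0)))

    @classmethod
    def _read_vcf_text(cls, path: str | Path) -> "GenotypePanel":
        ind_ids, rows, cols = [], [], []
        for line in open(path):
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                ind_ids = parts[9:]
                continue
            chrom, pos, vid, ref, alt = parts[:5]
            dos = np.array([g.count("1") for g in parts[9:]], dtype=np.int8)
            rows.append((vid, chrom, int(pos), alt, ref, dos.mean() / 2.0))
            cols.append(dos)
        snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "a1", "a2", "maf"])
        return cls(individual_ids=ind_ids, snps=snps,
                   dosages=np.column_stack(cols) if cols else np.empty((len(ind_ids), 0)))


# ----------------------------------------------------------------------
# GWAS summary text
# ----------------------------------------------------------------------

def write_gwas(gwas: GwasSummary, path: str | Path) -> None:
    gwas.table[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gwas(path: str | Path, scan_label: str = "overall") -> GwasSummary:
    t = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "A1": str, "A2": str})
    return GwasSummary(table=t, scan_label=scan_label)


# ----------------------------------------------------------------------
# Allele harmonization & input filters
# ----------------------------------------------------------------------

def harmonize_alleles(
    gwas: GwasSummary, panel: GenotypePanel, drop_ambiguous: bool = True
) -> GwasSummary:
    """Align a GWAS scan's alleles (and z signs) to the reference panel.

    SNPs absent from the panel are dropped.  When the scan's effect/other
    alleles are swapped relative to the panel, the z sign is flipped.
    Strand flips (complemented alleles) are resolved when unambiguous.
    A/T and C/G SNPs are dropped when ``drop_ambiguous`` (the default, as
    no allele-frequency disambiguation is attempted).  Irreconcilable
    allele pairs are dropped and recorded, never silently kept.
    The attached :class:`HarmonizationReport` counts every action;
    the operation is idempotent.
    """
    pan = panel.snps.set_index("snp_id")
    # fallback match on (chrom, pos) for SNPs whose id is absent
    pos_key = pd.MultiIndex.from_frame(panel.snps[["chrom", "pos"]].astype({"chrom": str}))
    pos_to_id = pd.Series(panel.snps["snp_id"].to_numpy(), index=pos_key)
    pos_to_id = pos_to_id[~pos_to_id.index.duplicated()]

    rep = HarmonizationReport(n_input=gwas.n_snps)
    rows = []
    for rec in gwas.table.itertuples(index=False):
        sid = rec.SNP
        if sid not in pan.index:
            key = (str(rec.CHR), rec.BP)
            sid = pos_to_id.get(key)
            if sid is None:
                rep.n_unmatched_dropped += 1
                continue
        p1, p2 = pan.at[sid, "a1"], pan.at[sid, "a2"]
        g1, g2 = rec.A1, rec.A2
        if drop_ambiguous and _is_ambiguous(g1, g2):
            rep.n_ambiguous_dropped += 1
            continue
        z = float(rec.Z)
        c1, c2 = _COMPLEMENT.get(g1), _COMPLEMENT.get(g2)
        if (g1, g2) == (p1, p2):
            pass
        elif (g2, g1) == (p1, p2):
            z = -z
            rep.n_sign_flipped += 1
        elif (c1, c2) == (p1, p2):
            rep.n_strand_flipped += 1
        elif (c2, c1) == (p1, p2):
            z = -z
            rep.n_sign_flipped += 1
            rep.n_strand_flipped += 1
        else:
            rep.n_irreconcilable_dropped += 1
            rep.irreconcilable_snps.append(str(sid))
            continue
        rows.append((sid, rec.CHR, rec.BP, p1, p2, z, rec.N))
        rep.n_kept += 1

    table = pd.DataFrame(rows, columns=GWAS_COLUMNS)
    return GwasSummary(table=table, scan_label=gwas.scan_label, harmonization=rep)


def apply_input_filters(
    gwas: GwasSummary,
    maf_by_snp: Mapping[str, float],
    maf_min: float,
    info_by_snp: Mapping[str, float],
    info_min: float,
) -> GwasSummary:
    """Retain only SNPs with MAF and imputation quality above thresholds.

    Retention is strict (``maf > maf_min`` and ``info > info_min``); SNPs
    with missing metadata are excluded and recorded in the report.
    """
    rep = FilterReport(n_input=gwas.n_snps)
    keep = []
    for rec in gwas.table.itertuples(index=False):
        sid = rec.SNP
        if sid not in maf_by_snp or sid not in info_by_snp:
            rep.n_missing_metadata += 1
            rep.missing_snps.append(str(sid))
            continue
        ok = True
        if not maf_by_snp[sid] > maf_min:
            rep.n_failed_maf += 1
            ok = False
        if not info_by_snp[sid] > info_min:
            rep.n_failed_info += 1
            ok = False
        keep.append(ok)
    matched = gwas.table[~gwas.table["SNP"].isin(rep.missing_snps)]
    table = matched[np.array(keep, dtype=bool)] if keep else matched.iloc[:0]
    rep.n_retained = len(table)
    return GwasSummary(table=table.reset_index(drop=True), scan_label=gwas.scan_label,
                       filter_report=rep)


# ----------------------------------------------------------------------
# Weight file dialect
# ----------------------------------------------------------------------

def write_weights(models: Iterable, path: str | Path) -> None:
    """Serialize weight models as versioned tab-delimited text.

    Layout: a version line, then per gene a ``#GENE`` metadata line
    followed by one ``gene_id snp_id a1 a2 weight`` row per SNP with a
    nonzero weight.
    """
    with open(path, "w") as fh:
        fh.write(f"##{_WEIGHT_FILE_VERSION}\n")
        fh.write("#GENE\tgene_id\tchrom\tstart\tend\tcis_start\tcis_end\tmethod"
                 "\tcv_r2\th2\th2_lrt_p\n")
        fh.write("gene_id\tsnp_id\ta1\ta2\tweight\n")
        for wm in models:
            fh.write(f"#GENE\t{wm.gene_id}\t{wm.chrom}\t{wm.start}\t{wm.end}"
                     f"\t{wm.cis_start}\t{wm.cis_end}\t{wm.method}"
                     f"\t{wm.cv_r2:.17g}\t{wm.h2:.17g}\t{wm.h2_lrt_p:.17g}\n")
            for sid, a1, a2, w in zip(wm.snp_ids, wm.a1, wm.a2, wm.weights):
                if w != 0.0:
                    fh.write(f"{wm.gene_id}\t{sid}\t{a1}\t{a2}\t{w:.17g}\n")


def read_weights(path: str | Path) -> list:
    from .weights import WeightModel  # local import avoids a cycle

    models: dict[str, WeightModel] = {}
    with open(path) as fh:
        header = fh.readline().strip()
        if header != f"##{_WEIGHT_FILE_VERSION}":
            raise ValueError(f"unrecognized weight file header: {header!r}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#GENE":
                if parts[1] == "gene_id":
                    continue  # column description line
                (gene_id, chrom, start, end, cis_start, cis_end,
                 method, cv_r2, h2, h2_lrt_p) = parts[1:]
                models[gene_id] = WeightModel(
                    gene_id=gene_id, method=method, snp_ids=[], a1=[], a2=[],
                    weights=np.empty(0), cv_r2=float(cv_r2), h2=float(h2),
                    h2_lrt_p=float(h2_lrt_p), chrom=chrom, start=int(start),
                    end=int(end), cis_start=int(cis_start), cis_end=int(cis_end))
            elif parts[0] == "gene_id":
                continue
            else:
                gene_id, sid, a1, a2, w = parts
                wm = models[gene_id]
                wm.snp_ids.append(sid)
                wm.a1.append(a1)
                wm.a2.append(a2)
                wm.weights = np.append(wm.weights, float(w))
    return list(models.values())


# ----------------------------------------------------------------------
# Packaged fixtures of the published result tables
# ----------------------------------------------------------------------

def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("twaskit.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh, sep="\t")


def load_table1_fixture() -> pd.DataFrame:
    """Published significant-gene table (per-gene h2, cv r2 and scan p-values)."""
    return _load_fixture("table1_fixture.tsv")


def load_table2_fixture() -> pd.DataFrame:
    """Published per-region conditional-analysis summary table."""
    return _load_fixture("table2_fixture.tsv")
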