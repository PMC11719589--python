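"""File formats and in-memory containers for the PGS analysis.

Genotypes travel as VCF 4.x (GT field only) or PLINK-style ``.raw``
additive-dosage text; the SNP panel, GWAS summary statistics, weight sets
and all result tables are TSV.  Dosages always count copies of the panel's
*counted allele*; files oriented the other way are flipped (``2 - g``) on
read, and a mismatch in either orientation is a hard error — no strand
inference is ever attempted, because silently guessing strand for A/T and
C/G SNPs corrupts downstream weights.

Coordinates are 1-based (VCF convention).  Panel positions are treated as
build-agnostic labels: SNPs are matched by rsID first, ``chrom:pos`` second.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan

SEVERITY_LEVELS = ("none", "mild", "moderate_severe")

#: Default 26-SNP panel of asthma drug-pathway genes: rsID, chromosome,
#: 1-based position, counted (rare/alternate) allele, other allele, and the
#: reference minor-allele frequency observed in the control group (fraction).
_DEFAULT_PANEL_ROWS = [
    # gene        chrom  pos         snp_id        counted other  maf
    ("SLC22A15",  "1",   116411750,  "rs1281744",  "C", "T", 0.1127),
    ("ALLC",      "2",   3700901,    "rs11123610", "C", "T", 0.3783),
    ("SPATS2L",   "2",   200858285,  "rs295137",   "T", "C", 0.3431),
    ("HRH1",      "3",   11275707,   "rs901865",   "A", "G", 0.1526),
    ("THRB",      "3",   24513842,   "rs892940",   "T", "C", 0.4393),
    ("FBXL7",     "5",   15836596,   "rs10044254", "C", "T", 0.2615),
    ("ALDH7A1",   "5",   125918148,  "rs13182402", "G", "A", 0.1035),
    ("NR3C1",     "5",   142778575,  "rs41423247", "G", "C", 0.3504),
    ("ADRB2",     "5",   148206440,  "rs1042713",  "A", "G", 0.4093),
    ("HRH2",      "5",   175041825,  "rs2067474",  "A", "G", 0.0381),
    ("LTC4S",     "5",   179153244,  "rs730012",   "C", "A", 0.2449),
    ("CMTR1",     "6",   37428577,   "rs2395672",  "A", "G", 0.2071),
    ("ARG1",      "6",   131895144,  "rs2781667",  "T", "C", 0.3316),
    ("TFT",       "6",   166499260,  "rs2305089",  "T", "C", 0.4532),
    ("GLCCI1",    "7",   800787,     "rs37973",    "C", "T", 0.4673),
    ("CRHR2",     "7",   30709475,   "rs2190242",  "C", "A", 0.3570),
    ("MAGI2",     "7",   77641211,   "rs2691529",  "C", "T", 0.2691),
    ("AOC1",      "7",   150557665,  "rs1049793",  "G", "C", 0.3477),
    ("ALOX5",     "10",  45221095,   "rs2115819",  "C", "T", 0.4796),
    ("PSAP",      "10",  73579217,   "rs11000016", "T", "C", 0.1592),
    ("LTA4",      "12",  94962684,   "rs2660845",  "G", "A", 0.2881),
    ("ARG2",      "14",  6811073,    "rs7140310",  "C", "A", 0.1516),
    ("ARG2",      "14",  67184754,   "rs3742879",  "G", "A", 0.2967),
    ("SCG3",      "15",  49756960,   "rs17525472", "C", "T", 0.1292),
    ("ADCY9",     "16",  3973437,    "rs2230739",  "C", "T", 0.3460),
    ("HRH4",      "18",  20310764,   "rs11665084", "T", "C", 0.1220),
]

PANEL_COLUMNS = ["snp_id", "chrom", "pos", "counted_allele", "other_allele",
                 "maf_reference", "gene"]


class FormatError(ValueError):
    """Malformed or schema-violating input file."""


class AlleleMismatchError(ValueError):
    """File alleles match the panel in neither orientation."""


@dataclass(frozen=True)
class VariantPanel:
    """The SNP panel: identifiers, coordinates, alleles, reference MAFs.

    ``counted_allele`` is the allele whose copies the dosage matrix counts
    (the rare/alternate allele of the panel table); ``maf_reference`` is the
    control-group minor-allele frequency as a fraction in [0, 0.5].
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing_cols = set(PANEL_COLUMNS[:-1]) - set(t.columns)
        if missing_cols:
            raise FormatError(f"panel missing columns: {sorted(missing_cols)}")
        if t["snp_id"].duplicated().any():
            dups = t.loc[t["snp_id"].duplicated(), "snp_id"].tolist()
            raise FormatError(f"duplicate panel snp_ids: {dups}")
        if (t["counted_allele"] == t["other_allele"]).any():
            raise FormatError("counted_allele equals other_allele for some SNP")
        if ((t["maf_reference"] < 0) | (t["maf_reference"] > 0.5)).any():
            raise FormatError("maf_reference outside [0, 0.5]")
        if (t["pos"] <= 0).any():
            raise FormatError("positions must be positive integers")
        object.__setattr__(self, "table",
                           t.reset_index(drop=True))

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def row(self, snp_id: str) -> pd.Series:
        hit = self.table[self.table["snp_id"] == snp_id]
        if hit.empty:
            raise KeyError(f"SNP {snp_id!r} not in panel")
        return hit.iloc[0]


def default_panel() -> VariantPanel:
    """The packaged 26-SNP asthma drug-pathway panel at control-group MAFs."""
    df = pd.DataFrame(
        _DEFAULT_PANEL_ROWS,
        columns=["gene", "chrom", "pos", "snp_id", "counted_allele",
                 "other_allele", "maf_reference"],
    )
    return VariantPanel(df[PANEL_COLUMNS])


def read_panel(path) -> VariantPanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "gene" not in df.columns:
        df["gene"] = ""
    return VariantPanel(df[PANEL_COLUMNS])


def write_panel(panel: VariantPanel, path) -> None:
    panel.table.to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeDataset:
    """Individuals x SNPs counted-allele dosages with phenotype labels.

    ``dosages[i, j]`` counts copies (0/1/2) of ``counted_allele[j]`` carried
    by sample ``i``; missing genotypes are NaN.  ``phenotype`` is 0 control /
    1 case; ``severity`` is one of ``none | mild | moderate_severe`` (cases
    only carry a non-``none`` label).  ``absent_snps`` lists panel SNPs that
    could not be resolved in the source file — reported, never silently
    dropped.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    counted_alleles: list[str]
    other_alleles: list[str]
    phenotype: np.ndarray | None = None
    severity: np.ndarray | None = None
    absent_snps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValueError("dosage matrix shape does not match labels")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=int)
            if not np.isin(self.phenotype, (0, 1)).all():
                raise ValueError("phenotype must be 0/1")
        if self.severity is not None:
            self.severity = np.asarray(self.severity, dtype=object)
            bad = set(self.severity) - set(SEVERITY_LEVELS)
            if bad:
                raise ValueError(f"unknown severity labels: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_ids.index(snp_id)]

    def require_phenotype(self) -> np.ndarray:
        if self.phenotype is None:
            raise ValueError("dataset carries no phenotype")
        if self.phenotype.sum() == 0 or self.phenotype.sum() == len(self.phenotype):
            raise ValueError("need at least one case and one control")
        return self.phenotype


# ---------------------------------------------------------------------------
# genotype file IO
# ---------------------------------------------------------------------------

def _orient(file_a1: str, file_a2: str, counted: str, other: str,
            snp_id: str) -> bool:
    """True if the file's counted orientation matches the panel; False if it
    must be flipped (2 - g); raise when neither orientation matches."""
    if (file_a1, file_a2) == (counted, other):
        return True
    if (file_a1, file_a2) == (other, counted):
        return False
    raise AlleleMismatchError(
        f"{snp_id}: file alleles {file_a1}/{file_a2} match panel "
        f"{counted}/{other} in neither orientation"
    )


def read_genotypes(path, panel: VariantPanel, dialect: str,
                   phenotype_path=None) -> GenotypeDataset:
    """Read a genotype file and orient dosages to the panel's counted allele.

    ``dialect`` is ``"vcf"`` or ``"plink_raw"``.  Panel SNPs missing from
    the file appear in ``absent_snps``.  An optional phenotype TSV
    (``sample_id``, ``phenotype``, optional ``severity``) attaches labels.
    """
    if dialect == "vcf":
        ds = _read_vcf(path, panel)
    elif dialect == "plink_raw":
        ds = _read_plink_raw(path, panel)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if phenotype_path is not None:
        attach_phenotype(ds, phenotype_path)
    return ds


def _read_vcf(path, panel: VariantPanel) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    by_id = {r.snp_id: r for _, r in panel.table.iterrows()}
    by_pos = {(r.chrom, r.pos): r for _, r in panel.table.iterrows()}

    cols: dict[str, np.ndarray] = {}
    alleles: dict[str, tuple[str, str]] = {}
    for var in vcf:
        row = by_id.get(var.ID)
        if row is None:
            row = by_pos.get((str(var.CHROM), var.POS))
        if row is None:
            continue
        if len(var.ALT) != 1:
            raise FormatError(f"{row.snp_id}: expected a biallelic record")
        same = _orient(var.ALT[0], var.REF, row.counted_allele,
                       row.other_allele, row.snp_id)
        # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        d = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        cols[row.snp_id] = d if same else 2.0 - d
        alleles[row.snp_id] = (row.counted_allele, row.other_allele)
    vcf.close()

    present = [s for s in panel.snp_ids if s in cols]
    absent = [s for s in panel.snp_ids if s not in cols]
    dos = (np.column_stack([cols[s] for s in present])
           if present else np.empty((len(samples), 0)))
    return GenotypeDataset(
        sample_ids=samples, snp_ids=present, dosages=dos,
        counted_alleles=[alleles[s][0] for s in present],
        other_alleles=[alleles[s][1] for s in present],
        absent_snps=absent,
    )


def _read_plink_raw(path, panel: VariantPanel) -> GenotypeDataset:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split()
    fixed = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if header[: len(fixed)] != fixed:
        raise FormatError(f"{path}:1: expected header starting {' '.join(fixed)}")
    snp_cols = header[len(fixed):]

    present, flip, c_all, o_all = [], [], [], []
    for col in snp_cols:
        if "_" not in col:
            raise FormatError(f"{path}:1: SNP column {col!r} lacks _<allele> suffix")
        snp_id, allele = col.rsplit("_", 1)
        try:
            row = panel.row(snp_id)
        except KeyError:
            continue
        if allele == row.counted_allele:
            flip.append(False)
        elif allele == row.other_allele:
            flip.append(True)
        else:
            raise AlleleMismatchError(
                f"{snp_id}: .raw counts allele {allele}, panel alleles are "
                f"{row.counted_allele}/{row.other_allele}")
        present.append(snp_id)
        c_all.append(row.counted_allele)
        o_all.append(row.other_allele)

    keep_idx = [i for i, col in enumerate(snp_cols)
                if col.rsplit("_", 1)[0] in set(present)]
    sample_ids, pheno, rows = [], [], []
    for ln, line in enumerate(lines[1:], start=2):
        parts = line.split()
        if len(parts) != len(header):
            raise FormatError(f"{path}:{ln}: expected {len(header)} fields, "
                              f"got {len(parts)}")
        sample_ids.append(parts[1])
        pheno.append(parts[5])
        vals = []
        for i in keep_idx:
            tok = parts[len(fixed) + i]
            if tok == "NA":
                vals.append(np.nan)
            else:
                try:
                    vals.append(float(tok))
                except ValueError:
                    raise FormatError(
                        f"{path}:{ln}: bad dosage {tok!r}") from None
        rows.append(vals)

    dos = np.asarray(rows, dtype=float) if rows else np.empty((0, len(present)))
    for j, do_flip in enumerate(flip):
        if do_flip and dos.size:
            dos[:, j] = 2.0 - dos[:, j]
    # .raw phenotype column: 1 control / 2 case; -9 or 0 = unknown
    ph = np.array([{"1": 0, "2": 1}.get(p, -1) for p in pheno])
    phenotype = ph if (ph >= 0).all() and len(ph) else None
    absent = [s for s in panel.snp_ids if s not in present]
    return GenotypeDataset(
        sample_ids=sample_ids, snp_ids=present, dosages=dos,
        counted_alleles=c_all, other_alleles=o_all,
        phenotype=phenotype, absent_snps=absent,
    )


def attach_phenotype(ds: GenotypeDataset, path) -> None:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "phenotype" not in df.columns:
        raise FormatError(f"{path}: need columns sample_id, phenotype")
    df = df.set_index("sample_id")
    try:
        df = df.loc[ds.sample_ids]
    except KeyError as e:
        raise FormatError(f"{path}: phenotype missing for sample {e}") from None
    ds.phenotype = df["phenotype"].to_numpy(dtype=int)
    if "severity" in df.columns:
        ds.severity = df["severity"].to_numpy(dtype=object)
    else:
        ds.severity = np.where(ds.phenotype == 1, "mild", "none").astype(object)
    ds.__post_init__()


def write_genotypes(ds: GenotypeDataset, path, dialect: str) -> None:
    """Write the dataset as VCF (REF=other, ALT=counted allele) or .raw."""
    if dialect == "vcf":
        _write_vcf(ds, path)
    elif dialect == "plink_raw":
        _write_plink_raw(ds, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def _write_vcf(ds: GenotypeDataset, path) -> None:
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##contig=<ID=1>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
              + "\t".join(ds.sample_ids) + "\n")
    # synthetic coordinates when the dataset carries none: chrom 1, 1-based
    for j, snp in enumerate(ds.snp_ids):
        gts = [_GT.get(g, "./.") for g in ds.dosages[:, j]]
        buf.write("\t".join([
            "1", str(j + 1), snp, ds.other_alleles[j], ds.counted_alleles[j],
            ".", "PASS", ".", "GT", *gts]) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _write_plink_raw(ds: GenotypeDataset, path) -> None:
    fixed = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    cols = [f"{s}_{a}" for s, a in zip(ds.snp_ids, ds.counted_alleles)]
    with open(path, "w") as fh:
        fh.write(" ".join(fixed + cols) + "\n")
        for i, sid in enumerate(ds.sample_ids):
            ph = "-9" if ds.phenotype is None else str(int(ds.phenotype[i]) + 1)
            vals = ["NA" if np.isnan(g) else str(int(g))
                    for g in ds.dosages[i]]
            fh.write(" ".join([sid, sid, "0", "0", "0", ph] + vals) + "\n")


def write_phenotype(ds: GenotypeDataset, path) -> None:
    sev = (ds.severity if ds.severity is not None
           else np.where(ds.phenotype == 1, "mild", "none"))
    pd.DataFrame({
        "sample_id": ds.sample_ids,
        "phenotype": ds.phenotype,
        "severity": sev,
    }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = ["snp_id", "effect_allele", "other_allele", "beta", "se"]


def read_summary_stats(path) -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV (snp_id, effect_allele,
    other_allele, beta, se[, n]); validates SE > 0 and rsID uniqueness."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"summary stats missing columns: {sorted(missing)}")
    if "n" not in df.columns:
        df["n"] = np.nan
    df = df[SUMMARY_COLUMNS + ["n"]].copy()
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    if df["snp_id"].duplicated().any():
        dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
        raise FormatError(f"duplicate snp_id in summary stats: {dups}")
    if len(df) and (df["se"] <= 0).any():
        bad = df.loc[df["se"] <= 0, "snp_id"].tolist()
        raise FormatError(f"non-positive SE for: {bad}")
    return df.reset_index(drop=True)


def write_summary_stats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(tables: dict[str, pd.DataFrame], out_dir) -> list[str]:
    """Write each result table as ``<name>.tsv`` under ``out_dir``.

    Numeric columns are formatted with 8 significant digits; column order is
    taken from the DataFrame, so identical inputs yield byte-identical files.
    Returns the written paths.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        p = out / f"{name}.tsv"
        tables[name].to_csv(p, sep="\t", index=False, float_format="%.8g",
                            lineterminator="\n")
        written.append(str(p))
    return written
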