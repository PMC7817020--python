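"""Rare-variant filtering, gene-level burden construction and effect
orientation.

Variants are consumed pre-annotated (gene symbol, consequence class,
population minor-allele frequency, CADD phred deleteriousness); annotation
itself is out of scope. The subject x gene burden matrix G0 encodes either
carrier status (0/1), counts, or signed status (-1/0/+1 after orientation by
the direction of each gene's case/control odds ratio).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "CONSEQUENCE_CLASSES",
    "DEFAULT_CONSEQUENCES",
    "LOF_CONSEQUENCES",
    "FilterCriteria",
    "BurdenMatrix",
    "EffectOrienter",
    "read_variant_table",
    "read_genotype_matrix",
    "filter_variants",
    "build_burden",
    "orient_effects",
]

CONSEQUENCE_CLASSES = ("missense", "stop_gain", "stop_loss", "frameshift", "other")
#: default deleterious set: exonic non-synonymous classes
DEFAULT_CONSEQUENCES = frozenset(
    {"missense", "stop_gain", "stop_loss", "frameshift"}
)
#: alternative high-impact set (loss-of-function); with this set the CADD
#: filter applies to stop-gain/stop-loss but frameshifts are CADD-exempt
LOF_CONSEQUENCES = frozenset({"stop_gain", "stop_loss", "frameshift"})

REQUIRED_COLUMNS = ("variant_id", "gene", "consequence", "maf", "cadd_phred")


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusion criteria for rare deleterious variants.

    A variant passes when ``maf < maf_max`` (strict), its consequence is in
    ``consequences``, and ``cadd_phred > cadd_min`` (strict) — unless it is a
    frameshift and ``frameshift_cadd_exempt`` is set, in which case the CADD
    condition is waived (frameshift indels often lack CADD scores).
    """

    maf_max: float = 0.01
    cadd_min: float = 20.0
    consequences: frozenset = DEFAULT_CONSEQUENCES
    frameshift_cadd_exempt: bool = False

    def __post_init__(self):
        if not 0 < self.maf_max < 1:
            raise ValueError("maf_max must be in (0, 1)")
        if self.cadd_min < 0:
            raise ValueError("cadd_min must be >= 0")


@dataclass
class BurdenMatrix:
    """Subject x gene rare-variant burden matrix (G0).

    ``encoding`` is one of ``status`` (0/1 carrier indicator), ``burden``
    (nonnegative variant counts) or ``signed_status`` (-1/0/+1 after effect
    orientation).
    """

    subjects: np.ndarray
    genes: np.ndarray
    values: sp.spmatrix
    encoding: str = "status"

    def __post_init__(self):
        self.subjects = np.asarray(self.subjects, dtype=object)
        self.genes = np.asarray(self.genes, dtype=object)
        self.values = sp.csr_matrix(self.values, dtype=float)
        if self.values.shape != (len(self.subjects), len(self.genes)):
            raise ValueError("values shape does not match subjects x genes")
        data = self.values.data
        if self.encoding == "status":
            if data.size and not np.all(np.isin(data, (0.0, 1.0))):
                raise ValueError("status encoding requires values in {0, 1}")
        elif self.encoding == "burden":
            if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
                raise ValueError("burden encoding requires nonnegative integers")
        elif self.encoding == "signed_status":
            if data.size and not np.all(np.isin(data, (-1.0, 0.0, 1.0))):
                raise ValueError("signed_status requires values in {-1, 0, +1}")
        else:
            raise ValueError(f"unknown encoding {self.encoding!r}")

    @property
    def shape(self):
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.toarray(), index=self.subjects, columns=self.genes
        )

    def to_tsv(self, path) -> None:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            self.to_frame().to_csv(fh, sep="\t", index_label="subject")


def read_variant_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read an annotated variant TSV with a header row.

    Required columns (after optional renaming through ``column_map``):
    variant_id, gene, consequence, maf, cadd_phred.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene": str})
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    return df


def read_genotype_matrix(path) -> pd.DataFrame:
    """Read a subject x variant 0/1 presence matrix TSV (subjects as rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_vcf_genotypes(path, variant_ids: list | None = None) -> pd.DataFrame:
    """Extract a subject x variant presence matrix from a VCF.

    Presence = at least one alternate allele at the variant in the subject
    (heterozygous and homozygous carriers count once). Variants are keyed by
    the ID column when set, else ``chrom:pos:ref:alt``. ``variant_ids``
    optionally restricts the columns. Requires cyvcf2.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    wanted = set(variant_ids) if variant_ids is not None else None
    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        if wanted is not None and vid not in wanted:
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(rec.gt_types)
        columns[vid] = np.isin(gt, (1, 3)).astype(int)
    return pd.DataFrame(columns, index=pd.Index(subjects, dtype=str))


def filter_variants(
    variants: pd.DataFrame, criteria: FilterCriteria | None = None
) -> pd.DataFrame:
    """Apply rare-deleterious inclusion criteria to an annotated variant table.

    Records with missing required annotations are excluded with a logged
    summary count. Row order of survivors is preserved.
    """
    if criteria is None:
        criteria = FilterCriteria()
    missing = [c for c in REQUIRED_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    required = variants[["gene", "consequence", "maf"]].notna().all(axis=1)
    # cadd may be absent only for CADD-exempt frameshifts
    cadd_ok_to_miss = (variants["consequence"] == "frameshift") & bool(
        criteria.frameshift_cadd_exempt
    )
    complete = required & (variants["cadd_phred"].notna() | cadd_ok_to_miss)
    n_incomplete = int((~complete).sum())
    if n_incomplete:
        logger.warning(
            "excluded %d variant records with missing annotations", n_incomplete
        )
    df = variants[complete]
    passes = (
        (df["maf"] < criteria.maf_max)
        & df["consequence"].isin(criteria.consequences)
        & (
            (df["cadd_phred"] > criteria.cadd_min)
            | (
                (df["consequence"] == "frameshift")
                & bool(criteria.frameshift_cadd_exempt)
            )
        )
    )
    return df[passes]


def build_burden(
    variants: pd.DataFrame,
    genotypes: pd.DataFrame,
    encoding: str = "status",
    genes: np.ndarray | None = None,
) -> BurdenMatrix:
    """Aggregate filtered variants into a subject x gene burden matrix.

    ``genotypes`` is a subject x variant 0/1 presence matrix whose columns
    cover every filtered variant. ``status`` marks a gene 1 when the subject
    carries at least one of its filtered variants; ``burden`` counts them.
    When ``genes`` (a companion network's gene order) is given, variants in
    genes absent from it are dropped with a logged count and network genes
    without variants get all-zero columns.
    """
    if encoding not in ("status", "burden"):
        raise ValueError("encoding must be 'status' or 'burden'")
    missing = [v for v in variants["variant_id"] if v not in genotypes.columns]
    if missing:
        raise ValueError(
            f"{len(missing)} filtered variants absent from genotype matrix; "
            f"first offenders: {missing[:10]}"
        )
    variant_genes = variants.set_index("variant_id")["gene"]
    if genes is not None:
        genes = np.asarray(genes, dtype=object)
        known = set(genes)
        dropped = sorted({g for g in variant_genes if g not in known})
        if dropped:
            logger.info(
                "dropped %d variant genes absent from the network", len(dropped)
            )
        variant_genes = variant_genes[variant_genes.isin(known)]
    else:
        genes = np.array(sorted(set(variant_genes)), dtype=object)
    gene_index = {g: i for i, g in enumerate(genes)}
    subjects = genotypes.index.to_numpy(dtype=object)
    rows, cols = [], []
    for vid, gene in variant_genes.items():
        presence = genotypes[vid].to_numpy(dtype=float)
        carriers = np.flatnonzero(presence >= 1)
        rows.append(carriers)
        cols.append(np.full(carriers.size, gene_index[gene]))
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
    counts = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(subjects), len(genes)),
    ).tocsr()  # duplicate (subject, gene) entries sum into counts
    if encoding == "status":
        counts.data = (counts.data > 0).astype(float)
    return BurdenMatrix(subjects, genes, counts, encoding=encoding)


class EffectOrienter(BaseEstimator, TransformerMixin):
    """Orient per-gene rare-variant effects by case/control odds ratio.

    For each gene a 2x2 carrier x case table is built over the phenotyped
    subjects passed to :meth:`fit`. Odds ratio > 1 calls the gene ``risk``,
    < 1 ``protective``; genes with OR exactly 1 or degenerate tables
    (all-carrier / no-carrier) are ``undetermined`` and left unchanged.
    Zero cells use the Haldane-Anscombe 0.5 correction for direction calling.

    ``mode``:

    - ``signed``: multiply protective columns by -1 (risk/undetermined kept);
    - ``zero_protective`` / ``zero_risk``: zero the respective columns;
    - ``none``: identity (metadata still computed).
    """

    def __init__(self, mode: str = "signed"):
        self.mode = mode

    def fit(self, X, y):
        if self.mode not in ("signed", "zero_protective", "zero_risk", "none"):
            raise ValueError(f"unknown mode {self.mode!r}")
        X = np.asarray(X.toarray() if sp.issparse(X) else X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.isnan(y).any():
            raise ValueError("phenotype must have no missing values for orientation")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of subjects")
        case = y == 1
        carrier = X != 0
        n_case, n_ctrl = int(case.sum()), int((~case).sum())
        a = carrier[case].sum(axis=0).astype(float)  # carriers among cases
        b = carrier[~case].sum(axis=0).astype(float)  # carriers among controls
        c = n_case - a
        d = n_ctrl - b
        tables = np.stack([a, b, c, d], axis=1)
        zero_cell = (tables == 0).any(axis=1)
        at, bt, ct, dt = (tables + 0.5 * zero_cell[:, None]).T
        odds = (at * dt) / (bt * ct)
        n_carriers = a + b
        degenerate = (n_carriers == 0) | (n_carriers == n_case + n_ctrl)
        direction = np.where(odds > 1, "risk", np.where(odds < 1, "protective", "undetermined"))
        direction = np.where(degenerate, "undetermined", direction)
        self.contingency_ = tables
        self.odds_ratio_ = odds
        self.direction_ = direction
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "direction_")
        sparse_in = sp.issparse(X)
        X = X.copy().astype(float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        if self.mode == "none":
            return X
        prot = self.direction_ == "protective"
        risk = self.direction_ == "risk"
        if self.mode == "signed":
            scale = np.where(prot, -1.0, 1.0)
        elif self.mode == "zero_protective":
            scale = np.where(prot, 0.0, 1.0)
        else:  # zero_risk
            scale = np.where(risk, 0.0, 1.0)
        if sparse_in:
            out = X @ sp.diags(scale)
            out.eliminate_zeros()
            return out.tocsr()
        return X * scale

    def summary(self, genes=None) -> pd.DataFrame:
        """Per-gene orientation metadata as a DataFrame."""
        check_is_fitted(self, "direction_")
        df = pd.DataFrame(
            self.contingency_,
            columns=["carrier_case", "carrier_ctrl", "noncarrier_case", "noncarrier_ctrl"],
        )
        df["odds_ratio"] = self.odds_ratio_
        df["direction"] = self.direction_
        if genes is not None:
            df.insert(0, "gene", np.asarray(genes, dtype=object))
        return df


def orient_effects(
    burden: BurdenMatrix,
    phenotype: np.ndarray,
    mode: str = "signed",
) -> tuple[BurdenMatrix, pd.DataFrame]:
    """Orient a status burden matrix by per-gene case/control odds ratios.

    ``phenotype`` is aligned to ``burden.subjects``; entries may be NaN for
    unphenotyped subjects — direction is called on the phenotyped subset but
    applied to every subject's column. Returns the oriented matrix together
    with the per-gene orientation table.
    """
    if burden.encoding != "status":
        raise ValueError("orientation expects a status-encoded burden matrix")
    phenotype = np.asarray(phenotype, dtype=float)
    if phenotype.shape[0] != len(burden.subjects):
        raise ValueError("phenotype length does not match subjects")
    mask = ~np.isnan(phenotype)
    orienter = EffectOrienter(mode=mode)
    orienter.fit(burden.values[mask], phenotype[mask])
    values = orienter.transform(burden.values)
    encoding = burden.encoding
    if mode == "signed" and (orienter.direction_ == "protective").any():
        encoding = "signed_status"
    out = BurdenMatrix(
        burden.subjects.copy(), burden.genes.copy(), values, encoding=encoding
    )
    return out, orienter.summary(genes=burden.genes)
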