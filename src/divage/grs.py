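"""Weighted-variant genetic risk score construction.

Builds the Alzheimer-disease genetic risk score (AD-GRS) used by the
downstream models: a weighted sum of effect-allele dosages over a panel of
risk variants, standardized by centering at the scored sample's mean and
dividing by its SD.  Also provides the APOE-region-excluded variant of the
score and APOE e4 allele counts from the rs429358/rs7412 diplotype.

Dosage input is either a VCF (DS dosages or GT hard calls, read with cyvcf2)
or a delimited participant x variant matrix.  Dosages are aligned so that
every variant counts its effect allele before weighting; strand-ambiguous
A/T and C/G variants are scored as-is with a warning unless strict mode
drops them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantWeight",
    "DosageMatrix",
    "GRSVector",
    "align_dosages",
    "compute_raw_score",
    "exclude_region",
    "apoe_e4_count",
    "zscore",
    "zscore_values",
    "read_weight_table",
    "write_weight_table",
    "read_dosage_matrix",
    "write_dosage_matrix",
    "read_vcf_dosages",
    "write_vcf_dosages",
    "demo_weights",
    "APOE_REGION_GRCH37",
]

_BASES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: chr19 interval (1-based, GRCh37) used by default for APOE-region exclusion;
#: spans TOMM40/APOE/APOC1 with a conventional +/- 1 Mb margin.
APOE_REGION_GRCH37 = ("19", 44_400_000, 46_500_000)


@dataclass(frozen=True)
class VariantWeight:
    """One scored variant: identifiers, allele pair and log-odds weight."""

    snv_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    weight: float

    def __post_init__(self) -> None:
        if self.effect_allele not in _BASES or self.other_allele not in _BASES:
            raise ValueError(
                f"{self.snv_id}: alleles must be single bases A/C/G/T, got "
                f"{self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snv_id}: effect and other allele are identical")
        if not np.isfinite(self.weight):
            raise ValueError(f"{self.snv_id}: weight must be finite")

    @property
    def is_strand_ambiguous(self) -> bool:
        """True for A/T and C/G pairs, which cannot be strand-resolved."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class DosageMatrix:
    """Participant x variant dosage matrix with counted-allele annotation.

    ``dosages`` holds values in [0, 2] (NaN for missing); ``counted_alleles``
    names, per variant, the allele the dosage counts.  ``positions`` and
    ``alleles`` carry optional (chrom, pos) and (counted, other) metadata
    used for VCF round-trips.
    """

    participant_ids: tuple[str, ...]
    snv_ids: tuple[str, ...]
    dosages: np.ndarray
    counted_alleles: dict[str, str]
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.participant_ids), len(self.snv_ids)):
            raise ValueError("dosage shape does not match id lists")
        with np.errstate(invalid="ignore"):
            if np.any((self.dosages < 0) | (self.dosages > 2)):
                raise ValueError("dosages must lie in [0, 2] or be missing")
        missing = set(self.snv_ids) - set(self.counted_alleles)
        if missing:
            raise ValueError(f"no counted-allele annotation for {sorted(missing)}")

    def column(self, snv_id: str) -> np.ndarray:
        return self.dosages[:, self.snv_ids.index(snv_id)]


@dataclass(frozen=True)
class GRSVector:
    """Per-participant raw and z-scored risk scores."""

    participant_ids: tuple[str, ...]
    raw_score: np.ndarray
    z_score: np.ndarray | None
    variant_count_used: int

    def to_frame(self) -> pd.DataFrame:
        data = {"participant_id": self.participant_ids, "grs_raw": self.raw_score}
        if self.z_score is not None:
            data["grs_z"] = self.z_score
        return pd.DataFrame(data)


def align_dosages(
    matrix: DosageMatrix,
    weights: Sequence[VariantWeight],
    ambiguous_policy: str = "warn",
) -> DosageMatrix:
    """Re-express dosages so every variant counts its weight's effect allele.

    If the matrix counts the other allele, dosage d becomes 2 - d; if its
    counted allele matches neither listed allele, that is an unrecoverable
    annotation conflict and an error is raised.  Strand-ambiguous (A/T, C/G)
    variants are scored as-is with a warning, or dropped when
    ``ambiguous_policy="drop"``.
    """
    if ambiguous_policy not in {"warn", "drop"}:
        raise ValueError("ambiguous_policy must be 'warn' or 'drop'")
    missing = [w.snv_id for w in weights if w.snv_id not in matrix.snv_ids]
    if missing:
        raise KeyError(f"variants absent from dosage matrix: {missing}")

    keep_ids: list[str] = []
    columns: list[np.ndarray] = []
    counted: dict[str, str] = {}
    for w in weights:
        if w.is_strand_ambiguous:
            if ambiguous_policy == "drop":
                warnings.warn(f"{w.snv_id}: strand-ambiguous {w.effect_allele}/"
                              f"{w.other_allele} pair dropped (strict mode)")
                continue
            warnings.warn(
                f"{w.snv_id}: strand-ambiguous {w.effect_allele}/{w.other_allele} "
                f"pair scored as-is; verify strand conventions"
            )
        col = matrix.column(w.snv_id)
        matrix_allele = matrix.counted_alleles[w.snv_id]
        if matrix_allele == w.effect_allele:
            aligned = col.copy()
        elif matrix_allele == w.other_allele:
            aligned = 2.0 - col
        else:
            raise ValueError(
                f"{w.snv_id}: matrix counts allele {matrix_allele!r}, which is "
                f"neither listed allele {w.effect_allele}/{w.other_allele}"
            )
        keep_ids.append(w.snv_id)
        columns.append(aligned)
        counted[w.snv_id] = w.effect_allele

    return DosageMatrix(
        participant_ids=matrix.participant_ids,
        snv_ids=tuple(keep_ids),
        dosages=np.column_stack(columns) if columns else np.empty((len(matrix.participant_ids), 0)),
        counted_alleles=counted,
        positions={s: matrix.positions[s] for s in keep_ids if s in matrix.positions},
        alleles={s: (counted[s], _other_of(weights, s)) for s in keep_ids},
    )


def _other_of(weights: Sequence[VariantWeight], snv_id: str) -> str:
    for w in weights:
        if w.snv_id == snv_id:
            return w.other_allele
    raise KeyError(snv_id)


def compute_raw_score(
    matrix: DosageMatrix,
    weights: Sequence[VariantWeight],
    on_missing: str = "impute",
) -> GRSVector:
    """Weighted sum of effect-allele dosages: raw_i = sum_j w_j d_ij.

    The matrix must already be aligned (each variant counting the weight's
    effect allele).  Missing dosages are imputed to the variant's sample
    mean dosage (2 x effect-allele frequency), or raise when
    ``on_missing="error"``.  Participants missing every dosage get a NaN
    score.
    """
    if on_missing not in {"impute", "error"}:
        raise ValueError("on_missing must be 'impute' or 'error'")
    order = [w.snv_id for w in weights]
    for snv_id in order:
        if snv_id not in matrix.snv_ids:
            raise KeyError(f"variant {snv_id} absent from dosage matrix")
        if matrix.counted_alleles[snv_id] != _effect_of(weights, snv_id):
            raise ValueError(
                f"{snv_id}: matrix counts {matrix.counted_alleles[snv_id]}, not the "
                f"effect allele; run align_dosages first"
            )
    idx = [matrix.snv_ids.index(s) for s in order]
    dosages = matrix.dosages[:, idx]
    w = np.array([wt.weight for wt in weights], dtype=float)

    nan_mask = np.isnan(dosages)
    if nan_mask.any():
        if on_missing == "error":
            n_bad = int(nan_mask.sum())
            raise ValueError(f"{n_bad} missing dosages and on_missing='error'")
        col_means = np.nanmean(dosages, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        dosages = np.where(nan_mask, col_means, dosages)

    raw = dosages @ w
    all_missing = nan_mask.all(axis=1) if nan_mask.any() else np.zeros(len(raw), bool)
    if all_missing.any():
        warnings.warn(f"{int(all_missing.sum())} participant(s) missing every "
                      f"dosage; score set to missing")
        raw = np.where(all_missing, np.nan, raw)
    return GRSVector(
        participant_ids=matrix.participant_ids,
        raw_score=raw,
        z_score=None,
        variant_count_used=len(order),
    )


def _effect_of(weights: Sequence[VariantWeight], snv_id: str) -> str:
    for w in weights:
        if w.snv_id == snv_id:
            return w.effect_allele
    raise KeyError(snv_id)


def exclude_region(
    weights: Sequence[VariantWeight],
    region: tuple[str, int, int] = APOE_REGION_GRCH37,
) -> list[VariantWeight]:
    """Drop variants inside a (chrom, start, end) 1-based closed interval.

    Used to build the APOE-region-excluded score.  The removal count is
    reported via a warning when any variant is dropped; an empty result
    (region covered everything) warns explicitly.
    """
    chrom, start, end = region
    if start > end:
        raise ValueError(f"region interval is inverted: {region}")
    chrom = str(chrom).removeprefix("chr")
    kept = [
        w
        for w in weights
        if not (str(w.chrom).removeprefix("chr") == chrom and start <= w.pos <= end)
    ]
    removed = len(weights) - len(kept)
    if removed:
        warnings.warn(f"excluded {removed} variant(s) in {region[0]}:{start}-{end}")
    if not kept:
        warnings.warn("region exclusion removed every variant; score is empty")
    return kept


#: unphased diplotype table: (rs429358 C count, rs7412 T count) -> e4 count.
#: rs429358-C marks e4/e1 haplotypes; rs7412-T marks e2/e1.  The (1, 1) cell
#: is genuinely ambiguous (e2/e4 vs e1/e3) and is resolved to e2/e4 because
#: the e1 haplotype is vanishingly rare.
_E4_TABLE: dict[tuple[int, int], tuple[int, bool]] = {
    (0, 0): (0, False),  # e3/e3
    (0, 1): (0, False),  # e2/e3
    (0, 2): (0, False),  # e2/e2
    (1, 0): (1, False),  # e3/e4
    (1, 1): (1, True),   # e2/e4 assumed over e1/e3
    (1, 2): (0, False),  # e1/e2 (forced: the C haplotype carries a T)
    (2, 0): (2, False),  # e4/e4
    (2, 1): (1, False),  # e1/e4
    (2, 2): (0, False),  # e1/e1
}


def apoe_e4_count(
    rs429358_c_dosage: int | np.ndarray,
    rs7412_t_dosage: int | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """APOE e4 allele count from the unphased rs429358/rs7412 diplotype.

    Arguments are hard-called allele counts: the C allele at rs429358 (the
    e4/e1-defining base) and the T allele at rs7412 (the e2/e1-defining
    base; C at rs7412 is the major allele shared by e3 and e4).  The double
    heterozygote is ambiguous between e2/e4 and e1/e3; it is resolved by the
    most-common-haplotype rule (e1 is vanishingly rare) to one e4 allele and
    flagged.

    Returns (e4_counts, ambiguity_flags) as integer / boolean arrays of the
    broadcast input shape (0-d inputs give 0-d arrays).
    """
    c1 = np.asarray(rs429358_c_dosage)
    t2 = np.asarray(rs7412_t_dosage)
    for name, arr in (("rs429358", c1), ("rs7412", t2)):
        as_float = arr.astype(float)
        if np.any(~np.isfinite(as_float)) or np.any(as_float != np.rint(as_float)):
            raise ValueError(
                f"{name} dosage is not an integer hard call; hard-call dosages "
                f"(round to 0/1/2) before counting e4 alleles"
            )
        if np.any((as_float < 0) | (as_float > 2)):
            raise ValueError(f"{name} dosage outside 0-2")
    c1, t2 = np.broadcast_arrays(c1.astype(int), t2.astype(int))
    counts = np.zeros(c1.shape, dtype=int)
    flags = np.zeros(c1.shape, dtype=bool)
    for (a, b), (count, flag) in _E4_TABLE.items():
        mask = (c1 == a) & (t2 == b)
        counts[mask] = count
        flags[mask] = flag
    return counts, flags


def zscore_values(raw: np.ndarray) -> np.ndarray:
    """(raw - mean) / SD over non-missing entries, sample SD (ddof=1)."""
    raw = np.asarray(raw, dtype=float)
    finite = raw[np.isfinite(raw)]
    if finite.size < 2:
        raise ValueError("need at least 2 non-missing scores to standardize")
    sd = finite.std(ddof=1)
    if sd == 0:
        raise ValueError("score SD is zero; cannot standardize a degenerate score")
    return (raw - finite.mean()) / sd


def zscore(scores: GRSVector) -> GRSVector:
    """Standardize raw scores against the scored sample (mean 0, SD 1)."""
    return replace(scores, z_score=zscore_values(scores.raw_score))


# ---------------------------------------------------------------------------
# file formats


def read_weight_table(path: str | Path) -> list[VariantWeight]:
    """Read a tab-delimited weight table.

    Header: snv_id, chrom, pos, effect_allele, other_allele, weight.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"snv_id", "chrom", "pos", "effect_allele", "other_allele", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    return [
        VariantWeight(
            snv_id=row.snv_id,
            chrom=str(row.chrom),
            pos=int(row.pos),
            effect_allele=row.effect_allele,
            other_allele=row.other_allele,
            weight=float(row.weight),
        )
        for row in df.itertuples()
    ]


def write_weight_table(weights: Sequence[VariantWeight], path: str | Path) -> None:
    pd.DataFrame([w.__dict__ for w in weights]).to_csv(path, sep="\t", index=False)


def read_dosage_matrix(path: str | Path, counted_alleles: dict[str, str]) -> DosageMatrix:
    """Read a delimited participant x variant dosage matrix.

    First column is the participant id; remaining columns are variant ids.
    ``counted_alleles`` must name the counted allele per variant column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return DosageMatrix(
        participant_ids=tuple(df.index.astype(str)),
        snv_ids=tuple(df.columns),
        dosages=df.to_numpy(dtype=float),
        counted_alleles=dict(counted_alleles),
    )


def write_dosage_matrix(matrix: DosageMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        matrix.dosages, index=list(matrix.participant_ids), columns=list(matrix.snv_ids)
    )
    df.index.name = "participant_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def write_vcf_dosages(matrix: DosageMatrix, path: str | Path) -> None:
    """Write the matrix as an uncompressed VCF with a DS FORMAT field.

    REF is the variant's other allele and ALT its counted (effect) allele,
    so DS counts the ALT allele as scoring tools expect.  Requires position
    and allele metadata on the matrix.
    """
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated ALT dose">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.participant_ids),
    ]
    order = sorted(
        matrix.snv_ids,
        key=lambda s: (matrix.positions[s][0], matrix.positions[s][1]),
    )
    for snv_id in order:
        chrom, pos = matrix.positions[snv_id]
        counted, other = matrix.alleles[snv_id]
        col = matrix.column(snv_id)
        fields = [chrom, str(pos), snv_id, other, counted, ".", "PASS", ".", "DS"]
        fields += ["." if np.isnan(d) else f"{d:g}" for d in col]
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def read_vcf_dosages(path: str | Path) -> DosageMatrix:
    """Read dosages from a VCF via cyvcf2 (DS field, else GT hard calls).

    Dosages count each record's ALT allele; the returned matrix carries that
    annotation so ``align_dosages`` can reconcile it with a weight table.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    participants = tuple(vcf.samples)
    snv_ids: list[str] = []
    columns: list[np.ndarray] = []
    counted: dict[str, str] = {}
    positions: dict[str, tuple[str, int]] = {}
    alleles: dict[str, tuple[str, str]] = {}
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        if len(variant.ALT) != 1:
            warnings.warn(f"{vid}: skipping non-biallelic record")
            continue
        ds = variant.format("DS")
        if ds is not None:
            col = ds.astype(float).reshape(-1)
            col = np.where(col < 0, np.nan, col)
        else:
            # gt_types: 0=hom-ref, 1=het, 2=hom-alt (cyvcf2 gts012), 3=unknown
            gts = variant.gt_types.astype(float)
            col = np.where(gts == 3, np.nan, gts)
        snv_ids.append(vid)
        columns.append(col)
        counted[vid] = variant.ALT[0]
        positions[vid] = (variant.CHROM, variant.POS)
        alleles[vid] = (variant.ALT[0], variant.REF)
    vcf.close()
    return DosageMatrix(
        participant_ids=participants,
        snv_ids=tuple(snv_ids),
        dosages=np.column_stack(columns) if columns else np.empty((len(participants), 0)),
        counted_alleles=counted,
        positions=positions,
        alleles=alleles,
    )


def demo_weights() -> list[VariantWeight]:
    """A synthetic 23-variant weight panel for examples and tests.

    Identifiers, positions and weights are fabricated (log-odds magnitudes
    typical of AD GWAS hits; one large APOE-region weight), NOT the published
    panel -- real weights are an input the user supplies.  Two variants sit
    inside the default APOE exclusion region on chromosome 19, so the
    region-excluded score keeps 21.
    """
    rng = np.random.default_rng(20220404)
    weights = []
    # non-complementary pairs only, so the panel is strand-unambiguous
    pairs = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
    for i in range(21):
        chrom = str(rng.integers(1, 23))
        ea, oa = pairs[int(rng.integers(0, len(pairs)))]
        if rng.random() < 0.5:
            ea, oa = oa, ea
        weights.append(
            VariantWeight(
                snv_id=f"rs9{i:06d}",
                chrom=chrom,
                pos=int(rng.integers(1_000_000, 200_000_000)),
                effect_allele=ea,
                other_allele=oa,
                weight=round(float(rng.normal(0.0, 0.08)), 4),
            )
        )
    # the APOE e4-defining pair, inside the default exclusion region
    weights.append(VariantWeight("rs429358", "19", 45_411_941, "C", "T", 1.12))
    weights.append(VariantWeight("rs7412", "19", 45_412_079, "T", "C", -0.47))
    return weights
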