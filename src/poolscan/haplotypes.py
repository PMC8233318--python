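"""Diplotype classification, allele polarization and association testing.

A set of strongly differentiated variants at one locus defines two reference
haplotypes, S and A (the spring- and autumn-associated alleles).  Diploid
genotypes over these variants are classified into S/S, A/A, S/A, recombinant
or unresolved without phasing: "S/A" means consistently heterozygous at every
diagnostic variant, an acknowledged unphased approximation.  An outgroup
species polarizes each variant (the allele matching the outgroup is
ancestral, the other derived), and a Fisher exact test quantifies the
haplotype-phenotype association.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

MISSING = {None, "", ".", "./.", "NA"}


@dataclass(frozen=True)
class HaplotypeDef:
    """Reference S/A haplotype definitions over an ordered variant panel.

    ``non_diagnostic_for_a`` lists variants that are polymorphic among A
    haplotypes (e.g. a missense SNP of recent origin): at such a variant a
    hom-A or heterozygous call does not break an A/A classification, but a
    hom-S call still does.
    """

    variant_ids: tuple[str, ...]
    s_alleles: tuple[str, ...]
    a_alleles: tuple[str, ...]
    outgroup_alleles: tuple[str | None, ...] = ()
    non_diagnostic_for_a: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        k = len(self.variant_ids)
        if len(self.s_alleles) != k or len(self.a_alleles) != k:
            raise ConfigError("allele lists must match variant_ids in length")
        if self.outgroup_alleles and len(self.outgroup_alleles) != k:
            raise ConfigError("outgroup_alleles must match variant_ids in length")
        for vid, s, a in zip(self.variant_ids, self.s_alleles, self.a_alleles):
            if s == a:
                raise ConfigError(f"S and A alleles identical at {vid}")
        unknown = self.non_diagnostic_for_a - set(self.variant_ids)
        if unknown:
            raise ConfigError(f"non_diagnostic_for_a names unknown variants {sorted(unknown)}")


def example_locus_definition() -> HaplotypeDef:
    """A six-variant panel with the canonical structure of a differentiated
    seasonal-spawning locus: two non-coding SNPs, two missense SNPs, the
    insertion presence/absence (I/D) and a tandem-repeat copy-number variant.

    SNP3 is marked non-diagnostic for A (polymorphic among A haplotypes), and
    the outgroup carries the ancestral state: it matches the A allele at four
    variants (S derived there) and the S allele at SNP3 and the insertion
    variant (where the internal-sequence loss is derived on A).
    """
    return HaplotypeDef(
        variant_ids=("SNP1", "SNP2", "SNP3", "SNP4", "SV5.2kb", "repeat22aa"),
        s_alleles=("T", "A", "C", "A", "I", "3"),
        a_alleles=("C", "G", "A", "C", "D", "5"),
        outgroup_alleles=("C", "G", "C", "C", "I", "5"),
        non_diagnostic_for_a=frozenset({"SNP3"}),
    )


def _parse_call(value) -> tuple[str, str] | None:
    if isinstance(value, tuple):
        return value
    if value in MISSING or (isinstance(value, float) and np.isnan(value)):
        return None
    parts = str(value).split("/")
    if len(parts) != 2 or any(p in MISSING for p in parts):
        return None
    return parts[0], parts[1]


def classify_diplotype(genotype_row: Mapping[str, object], definition: HaplotypeDef,
                       max_missing: int = 1) -> str:
    """Classify one individual's unphased genotypes against the S/A panel.

    Returns one of ``"S/S"``, ``"A/A"``, ``"S/A"``, ``"recombinant"``,
    ``"unresolved"`` (more than ``max_missing`` missing calls).  Alleles that
    match neither reference haplotype raise, naming the variant.
    """
    states = []  # (variant, state) with state in {"S", "A", "H"}
    n_missing = 0
    for vid, s_al, a_al in zip(definition.variant_ids, definition.s_alleles,
                               definition.a_alleles):
        call = _parse_call(genotype_row.get(vid))
        if call is None:
            n_missing += 1
            continue
        coded = []
        for allele in call:
            if allele == s_al:
                coded.append("S")
            elif allele == a_al:
                coded.append("A")
            else:
                raise ConfigError(f"unknown allele {allele!r} at variant {vid}")
        pair = frozenset(coded)
        if pair == frozenset({"S"}):
            states.append((vid, "S"))
        elif pair == frozenset({"A"}):
            states.append((vid, "A"))
        else:
            states.append((vid, "H"))
    if n_missing > max_missing:
        return "unresolved"
    if not states:
        return "unresolved"
    lenient = definition.non_diagnostic_for_a
    if all(st == "S" for _, st in states):
        return "S/S"
    if all(st == "A" or (vid in lenient and st in ("A", "H")) for vid, st in states):
        return "A/A"
    if all(st == "H" for _, st in states):
        return "S/A"
    return "recombinant"


def classify_cohort(genotypes: pd.DataFrame, definition: HaplotypeDef,
                    max_missing: int = 1) -> pd.Series:
    """Vector version of :func:`classify_diplotype` over a genotype table
    (one row per individual, one column per variant)."""
    return genotypes.apply(
        lambda row: classify_diplotype(row.to_dict(), definition, max_missing), axis=1)


def polarize_variants(definition: HaplotypeDef) -> tuple[dict[str, str], int]:
    """Polarize each variant with the outgroup allele.

    The haplotype allele matching the outgroup is ancestral; the other is
    derived.  Returns a per-variant map to ``"S"``/``"A"``/``"unresolved"``
    (which haplotype carries the derived allele) and the count of S-derived
    variants.
    """
    if not definition.outgroup_alleles or all(o in MISSING for o in definition.outgroup_alleles):
        raise ConfigError("polarization requires outgroup alleles for >= 1 variant")
    out: dict[str, str] = {}
    n_s_derived = 0
    for vid, s_al, a_al, og in zip(definition.variant_ids, definition.s_alleles,
                                   definition.a_alleles, definition.outgroup_alleles):
        if og in MISSING:
            out[vid] = "unresolved"
        elif og == a_al:
            out[vid] = "S"
            n_s_derived += 1
        elif og == s_al:
            out[vid] = "A"
        else:
            out[vid] = "unresolved"
    return out, n_s_derived


def fisher_association(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Fisher exact test of a 2x2 haplotype-class x phenotype table.

    Two-sided p sums hypergeometric tables no more probable than the observed
    one.  The odds ratio is the sample (a*d)/(b*c), with 0.5 added to every
    cell only when some cell is zero (reported as a conditioned estimate).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ConfigError("table must be 2x2 with non-negative counts")
    if t.sum() == 0:
        raise ConfigError("all-zero table")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = (float(x) for x in t.ravel())
    if 0.0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return odds, float(p)


def association_summary(classes: pd.Series, phenotypes: pd.Series,
                        class_a: str = "S/S", class_b: str = "A/A",
                        pheno_a: str = "spring", pheno_b: str = "autumn") -> dict:
    """Build the 2x2 table of pure diplotype classes vs phenotypes and test it."""
    mask = classes.isin([class_a, class_b]) & phenotypes.isin([pheno_a, pheno_b])
    cls, phe = classes[mask], phenotypes[mask]
    table = [[int(((cls == class_a) & (phe == pheno_a)).sum()),
              int(((cls == class_a) & (phe == pheno_b)).sum())],
             [int(((cls == class_b) & (phe == pheno_a)).sum()),
              int(((cls == class_b) & (phe == pheno_b)).sum())]]
    odds, p = fisher_association(table)
    return {"table": table, "odds_ratio": odds, "p_two_sided": p,
            "classes": (class_a, class_b), "phenotypes": (pheno_a, pheno_b)}


def read_genotype_table(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a genotype TSV (individual, phenotype, one slash-separated column
    per variant); returns (genotypes, phenotypes) indexed by individual."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("individual")
    phenotypes = df.pop("phenotype")
    return df, phenotypes
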