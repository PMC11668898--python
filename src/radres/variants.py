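"""Multi-caller somatic SNV consensus and 96-context mutation catalogues.

Somatic variants are called per replicate by several independent callers
(e.g. Mutect2, Strelka2, Lancet). A site is accepted as a true acquired
variant only when at least ``min_callers`` distinct callers report it within
a replicate, in at least ``min_replicates`` replicates. Accepted SNVs are
binned into the standard 96 pyrimidine-centred trinucleotide context classes
(``A[C>T]G`` etc.) to form the catalogue consumed by signature refitting.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The six pyrimidine-strand substitution classes, COSMIC order.
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 context labels "5'[ref>alt]3'" in COSMIC order: substitution-major,
#: then flanking bases alphabetically.
CONTEXTS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
_CONTEXT_INDEX = {label: i for i, label in enumerate(CONTEXTS_96)}

REQUIRED_COLUMNS = ("sample_id", "replicate_id", "caller_id", "chrom", "pos", "ref", "alt")
OPTIONAL_COLUMNS = ("gene", "effect", "context")

EFFECTS = ("synonymous", "non_synonymous", "other")


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class VariantCall:
    """One caller's report of a single-nucleotide variant in one replicate."""

    sample_id: str
    replicate_id: str
    caller_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str | None = None
    effect: str | None = None
    context: str | None = None  # 3-mer centred on pos, reference strand

    def __post_init__(self):
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ConsensusVariant:
    """A variant key that survived the caller-vote / replicate-consensus rule."""

    key: tuple[str, int, str, str]
    callers_by_replicate: dict[str, frozenset[str]]
    n_supporting_replicates: int


def read_variant_table(path: str | Path) -> tuple[list[VariantCall], int]:
    """Read a MAF-like tab-delimited variant table.

    Returns ``(calls, n_skipped)`` where ``n_skipped`` counts indel /
    multi-nucleotide rows excluded by the SNV-only rule. Missing mandatory
    columns raise ``ValueError`` naming the column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"variant table {path} is missing mandatory column '{col}'")
    calls: list[VariantCall] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES or ref == alt:
            n_skipped += 1
            continue
        calls.append(
            VariantCall(
                sample_id=str(row.sample_id),
                replicate_id=str(row.replicate_id),
                caller_id=str(row.caller_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=ref,
                alt=alt,
                gene=getattr(row, "gene", None) if "gene" in df.columns else None,
                effect=getattr(row, "effect", None) if "effect" in df.columns else None,
                context=getattr(row, "context", None) if "context" in df.columns else None,
            )
        )
    if n_skipped:
        logger.info("read_variant_table(%s): skipped %d non-SNV rows", path, n_skipped)
    return calls, n_skipped


def write_variant_table(calls: list[VariantCall], path: str | Path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "replicate_id": c.replicate_id,
            "caller_id": c.caller_id,
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "gene": c.gene if c.gene is not None else "",
            "effect": c.effect if c.effect is not None else "",
            "context": c.context if c.context is not None else "",
        }
        for c in calls
    ]
    cols = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def consensus_filter(
    calls: list[VariantCall],
    min_callers: int = 2,
    min_replicates: int = 2,
    mode: str = "per_replicate",
) -> list[ConsensusVariant]:
    """Apply the caller-vote and replicate-consensus rule.

    ``mode="per_replicate"`` (default): a key is retained iff the number of
    replicates in which ≥ ``min_callers`` distinct callers report it is
    ≥ ``min_replicates``.

    ``mode="per_caller"`` is the alternative reading of "consensus in at
    least duplicates": a key is retained iff ≥ ``min_callers`` callers each
    report it in ≥ ``min_replicates`` replicates.
    """
    if min_callers < 1 or min_replicates < 1:
        raise ValueError("min_callers and min_replicates must be >= 1")
    if mode not in ("per_replicate", "per_caller"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) > 1:
        raise ValueError(f"consensus_filter expects one sample, got {sorted(sample_ids)}")

    support: dict[tuple, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for c in calls:
        support[c.key][c.replicate_id].add(c.caller_id)

    out: list[ConsensusVariant] = []
    for key, by_rep in support.items():
        if mode == "per_replicate":
            n_sup = sum(1 for callers in by_rep.values() if len(callers) >= min_callers)
            keep = n_sup >= min_replicates
        else:
            reps_per_caller = Counter(
                caller for callers in by_rep.values() for caller in callers
            )
            n_ok = sum(1 for n in reps_per_caller.values() if n >= min_replicates)
            keep = n_ok >= min_callers
            n_sup = sum(1 for callers in by_rep.values() if len(callers) >= min_callers)
        if keep:
            out.append(
                ConsensusVariant(
                    key=key,
                    callers_by_replicate={r: frozenset(s) for r, s in by_rep.items()},
                    n_supporting_replicates=n_sup,
                )
            )
    out.sort(key=lambda v: v.key)
    return out


def count_by_effect(
    consensus: list[ConsensusVariant], calls: list[VariantCall]
) -> dict[str, int]:
    """Tally consensus SNVs by functional effect.

    Effect annotations may disagree across callers/replicates; the majority
    annotation wins, ties and missing annotations fall to ``other``.
    """
    ann: dict[tuple, Counter] = defaultdict(Counter)
    for c in calls:
        if c.effect in ("synonymous", "non_synonymous"):
            ann[c.key][c.effect] += 1
    counts = {e: 0 for e in EFFECTS}
    for v in consensus:
        votes = ann.get(v.key)
        if not votes:
            counts["other"] += 1
            continue
        best = votes.most_common()
        if len(best) > 1 and best[0][1] == best[1][1]:
            counts["other"] += 1
        else:
            counts[best[0][0]] += 1
    counts["total"] = len(consensus)
    return counts


def context_bin(ref: str, alt: str, context: str) -> str:
    """Map an SNV with its reference-strand 3-mer to its 96-class label.

    Purine-reference variants are reverse-complemented onto the pyrimidine
    strand first (the standard SBS convention).
    """
    if len(context) != 3:
        raise ValueError(f"context must be a 3-mer, got {context!r}")
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]!r} != ref {ref!r}")
    if ref in ("G", "A"):
        ref, alt, context = _COMPLEMENT[ref], _COMPLEMENT[alt], revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def build_96_catalogue(
    consensus: list[ConsensusVariant],
    contexts: dict[tuple[str, int, str, str], str],
) -> pd.Series:
    """Bin consensus SNVs into the 96 pyrimidine-centred context classes.

    Returns an integer Series indexed by :data:`CONTEXTS_96` whose sum equals
    the number of consensus variants.
    """
    counts = np.zeros(96, dtype=int)
    for v in consensus:
        chrom, pos, ref, alt = v.key
        try:
            ctx = contexts[v.key]
        except KeyError:
            raise ValueError(f"no context provided for variant {v.key}") from None
        counts[_CONTEXT_INDEX[context_bin(ref, alt, ctx)]] += 1
    return pd.Series(counts, index=list(CONTEXTS_96), name="count")


def write_catalogue(catalogue: pd.Series, path: str | Path) -> None:
    catalogue.rename_axis("context").to_csv(path, sep="\t")


def read_catalogue(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0]
    if list(s.index) != list(CONTEXTS_96):
        raise ValueError(f"catalogue {path} is not in COSMIC 96-context order")
    return s.astype(int).rename("count")
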