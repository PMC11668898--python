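#!/usr/bin/env python
"""Consensus SNV calling on the simulated multi-caller tables.

Applies the 2-of-3-callers / 2-of-3-replicates voting rule, tallies the
consensus variants by functional effect, scores recovery against the
planted truth, and builds the 96-context catalogue for signature refitting.
"""

from pathlib import Path

import pandas as pd

from radres import variants as VAR

IN = Path("results/inputs")
OUT = Path("results/variants")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    calls, n_skipped = VAR.read_variant_table(IN / "caller_calls.tsv")
    truth = pd.read_csv(IN / "truth_variants.tsv", sep="\t")
    truth_keys = {
        (r.chrom, r.pos, r.ref, r.alt) for r in truth.itertuples()
    }

    consensus = VAR.consensus_filter(calls, min_callers=2, min_replicates=2)
    recovered = sum(1 for v in consensus if v.key in truth_keys)
    false_kept = len(consensus) - recovered
    effects = VAR.count_by_effect(consensus, calls)

    contexts = {(r.chrom, r.pos, r.ref, r.alt): r.context for r in truth.itertuples()}
    contexts.update({c.key: c.context for c in calls if c.context})
    catalogue = VAR.build_96_catalogue(consensus, contexts)
    VAR.write_catalogue(catalogue, OUT / "consensus_catalogue.tsv")

    rows = [{"chrom": v.key[0], "pos": v.key[1], "ref": v.key[2], "alt": v.key[3],
             "n_supporting_replicates": v.n_supporting_replicates,
             "is_true_somatic": int(v.key in truth_keys)} for v in consensus]
    pd.DataFrame(rows).to_csv(OUT / "consensus_variants.tsv", sep="\t", index=False)

    print(f"{len(calls)} calls read ({n_skipped} non-SNV rows skipped)")
    print(f"consensus: {len(consensus)} variants "
          f"({recovered}/{len(truth)} true recovered, {false_kept} false kept)")
    print(f"effects: {effects}")
    print(f"catalogue total {int(catalogue.sum())} -> {OUT/'consensus_catalogue.tsv'}")


if __name__ == "__main__":
    main()
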