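"""Consensus voting, effect tallies, and 96-context catalogue construction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from radres.variants import (
    CONTEXTS_96,
    VariantCall,
    build_96_catalogue,
    consensus_filter,
    context_bin,
    count_by_effect,
    read_catalogue,
    read_variant_table,
    revcomp,
    write_catalogue,
    write_variant_table,
)
from .conftest import make_call

BASES = "ACGT"


def brute_force_consensus(calls, min_callers=2, min_replicates=2):
    """Independent oracle: enumerate all (key, replicate, caller) triples."""
    keys = {c.key for c in calls}
    kept = []
    for key in keys:
        n_good_reps = 0
        for rep in {c.replicate_id for c in calls}:
            callers = {
                c.caller_id for c in calls if c.key == key and c.replicate_id == rep
            }
            if len(callers) >= min_callers:
                n_good_reps += 1
        if n_good_reps >= min_replicates:
            kept.append(key)
    return sorted(kept)


class TestConsensusFilter:
    def test_two_callers_two_replicates_retained(self):
        calls = [make_call(caller=c, rep=r) for c in ("m", "s") for r in ("rep1", "rep2")]
        out = consensus_filter(calls)
        assert len(out) == 1
        assert out[0].n_supporting_replicates == 2

    def test_three_callers_single_replicate_dropped(self):
        calls = [make_call(caller=c, rep="rep1") for c in ("m", "s", "l")]
        assert consensus_filter(calls) == []

    def test_matches_brute_force_on_random_instances(self, rng):
        callers, reps = ["m", "s", "l"], ["rep1", "rep2", "rep3"]
        for _ in range(60):
            n = int(rng.integers(1, 50))
            calls = []
            for _ in range(int(rng.integers(1, 120))):
                pos = int(rng.integers(1, n + 1))
                calls.append(
                    make_call(pos=pos, caller=str(rng.choice(callers)),
                              rep=str(rng.choice(reps)))
                )
            got = [v.key for v in consensus_filter(calls)]
            assert got == brute_force_consensus(calls)

    @pytest.mark.parametrize("param", ["min_callers", "min_replicates"])
    def test_stricter_thresholds_shrink_the_set(self, rng, param):
        calls = [
            make_call(pos=int(rng.integers(1, 20)), caller=str(rng.choice(list("msl"))),
                      rep=f"rep{rng.integers(1, 4)}")
            for _ in range(150)
        ]
        previous = None
        for value in (1, 2, 3):
            kwargs = {param: value}
            keys = {v.key for v in consensus_filter(calls, **kwargs)}
            if previous is not None:
                assert keys <= previous
            previous = keys

    def test_output_keys_subset_of_input(self, rng):
        calls = [make_call(pos=int(rng.integers(1, 10))) for _ in range(30)]
        out = {v.key for v in consensus_filter(calls, min_callers=1, min_replicates=1)}
        assert out <= {c.key for c in calls}

    def test_mixed_samples_rejected(self):
        calls = [make_call(sample="A"), make_call(sample="B")]
        with pytest.raises(ValueError, match="sample"):
            consensus_filter(calls)

    def test_per_caller_mode_differs_on_split_support(self):
        # two callers, each in a different pair of replicates: no replicate
        # ever has 2 callers, but each caller is reproducible
        calls = [
            make_call(caller="m", rep="rep1"), make_call(caller="m", rep="rep2"),
            make_call(caller="s", rep="rep2"), make_call(caller="s", rep="rep3"),
        ]
        assert consensus_filter(calls, mode="per_replicate") == []
        assert len(consensus_filter(calls, mode="per_caller")) == 1


class TestEffectCounts:
    def test_partition_and_majority(self):
        calls = [
            make_call(pos=1, caller=c, rep=r, effect="synonymous")
            for c in "ms" for r in ("rep1", "rep2")
        ] + [
            make_call(pos=2, caller=c, rep=r, effect="non_synonymous")
            for c in "ms" for r in ("rep1", "rep2")
        ]
        cons = consensus_filter(calls)
        counts = count_by_effect(cons, calls)
        assert counts == {"synonymous": 1, "non_synonymous": 1, "other": 0, "total": 2}

    def test_annotation_tie_falls_to_other(self):
        calls = [
            make_call(pos=1, caller="m", rep="rep1", effect="synonymous"),
            make_call(pos=1, caller="s", rep="rep1", effect="non_synonymous"),
            make_call(pos=1, caller="m", rep="rep2", effect="synonymous"),
            make_call(pos=1, caller="s", rep="rep2", effect="non_synonymous"),
        ]
        cons = consensus_filter(calls)
        assert count_by_effect(cons, calls)["other"] == 1

    def test_empty_consensus_all_zero(self):
        assert count_by_effect([], []) == {
            "synonymous": 0, "non_synonymous": 0, "other": 0, "total": 0,
        }


class TestContextBinning:
    def test_pyrimidine_reference_bins_directly(self):
        assert context_bin("C", "T", "ACA") == "A[C>T]A"

    def test_purine_reference_reverse_complemented(self):
        assert context_bin("G", "A", "TGT") == "A[C>T]A"

    def test_mismatched_context_rejected(self):
        with pytest.raises(ValueError, match="middle"):
            context_bin("C", "T", "AGA")

    def test_random_snvs_match_naive_oracle_and_total(self, rng):
        comp = dict(zip("ACGT", "TGCA"))
        cons, contexts = [], {}
        for i in range(200):
            ref = str(rng.choice(list(BASES)))
            alt = str(rng.choice([b for b in BASES if b != ref]))
            ctx = str(rng.choice(list(BASES))) + ref + str(rng.choice(list(BASES)))
            calls = [make_call(pos=i + 1, ref=ref, alt=alt, caller=c, rep=r)
                     for c in "ms" for r in ("rep1", "rep2")]
            cons.extend(consensus_filter(calls))
            contexts[("chr1", i + 1, ref, alt)] = ctx
        cat = build_96_catalogue(cons, contexts)
        assert cat.sum() == 200
        # naive per-variant oracle
        naive = {label: 0 for label in CONTEXTS_96}
        for v in cons:
            _, _, ref, alt = v.key
            ctx = contexts[v.key]
            if ref in "GA":
                ref, alt = comp[ref], comp[alt]
                ctx = ctx[::-1].translate(str.maketrans("ACGT", "TGCA"))
            naive[f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"] += 1
        assert dict(cat) == naive

    def test_catalogue_roundtrip(self, tmp_path, rng):
        cat = pd.Series(rng.integers(0, 20, 96), index=list(CONTEXTS_96), name="count")
        write_catalogue(cat, tmp_path / "cat.tsv")
        back = read_catalogue(tmp_path / "cat.tsv")
        assert (back == cat).all()


class TestVariantTableIO:
    def test_roundtrip_and_snv_skip(self, tmp_path):
        path = tmp_path / "calls.tsv"
        calls = [make_call(pos=p, effect="synonymous", context="ACA") for p in (1, 2, 3)]
        write_variant_table(calls, path)
        # append an indel row, which must be skipped with a count
        with open(path, "a") as fh:
            fh.write("S\trep1\tm\tchr1\t9\tAT\tA\t\t\t\n")
        back, skipped = read_variant_table(path)
        assert len(back) == 3 and skipped == 1
        assert [c.pos for c in back] == [1, 2, 3]
        assert back[0].effect == "synonymous"

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\treplicate_id\tcaller_id\tchrom\tref\talt\n")
        with pytest.raises(ValueError, match="pos"):
            read_variant_table(path)

    def test_invalid_call_construction(self):
        with pytest.raises(ValueError):
            VariantCall("S", "rep1", "m", "chr1", 1, "C", "C")
        with pytest.raises(ValueError):
            VariantCall("S", "rep1", "m", "chr1", 1, "N", "T")


def test_revcomp():
    assert revcomp("ACG") == "CGT"


# hypothesis property: the consensus rule is monotone in both thresholds and
# never invents keys, for arbitrary call multisets
from hypothesis import given, settings, strategies as st


@st.composite
def call_sets(draw):
    n = draw(st.integers(1, 60))
    return [
        make_call(
            pos=draw(st.integers(1, 12)),
            caller=draw(st.sampled_from(["m", "s", "l"])),
            rep=draw(st.sampled_from(["rep1", "rep2", "rep3"])),
        )
        for _ in range(n)
    ]


@settings(max_examples=30, derandomize=True, deadline=None)
@given(calls=call_sets(), mc=st.integers(1, 3), mr=st.integers(1, 3))
def test_consensus_monotone_and_bounded(calls, mc, mr):
    keys = {v.key for v in consensus_filter(calls, min_callers=mc, min_replicates=mr)}
    assert keys <= {c.key for c in calls}
    stricter = {
        v.key
        for v in consensus_filter(calls, min_callers=mc + 1, min_replicates=mr)
    }
    assert stricter <= keys
    assert [v.key for v in consensus_filter(calls, min_callers=mc, min_replicates=mr)] \
        == brute_force_consensus(calls, mc, mr)
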