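"""Window enumeration and prefilter behaviour against brute-force oracles."""

import numpy as np
import pytest

from vacinus.peptides import (
    CandidatePeptide,
    TpmGate,
    VariantClass,
    VariantRecord,
    enumerate_windows,
    filter_anchor,
    filter_binding,
    filter_expression,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def naive_windows(mt: str, altered: set[int], lengths=(9, 10)) -> set[str]:
    """Independent oracle: all full-length substrings covering an altered
    position, by exhaustive scan."""
    out = set()
    for L in lengths:
        for s in range(len(mt) - L + 1):
            if any(s + 1 <= p <= s + L for p in altered):
                out.add(mt[s : s + L])
    return out


def test_interior_missense_yields_window_per_length(missense_variant):
    cands = enumerate_windows(missense_variant)
    # position 10 of a 30-mer is interior for both lengths: 9 + 10 windows
    assert len(cands) == 19
    assert sum(len(c) == 9 for c in cands) == 9
    assert sum(len(c) == 10 for c in cands) == 10
    for c in cands:
        assert c.mt_seq in missense_variant.mt_protein
        assert c.wt_seq == missense_variant.wt_protein[
            c.windows[0] - 1 : c.windows[0] - 1 + len(c)
        ]
        assert c.mut_positions


def test_terminal_missense_single_start_position():
    wt = "ARNDCQEGHILKMFPSTWYV"
    mt = "W" + wt[1:]
    v = VariantRecord("v", "G", VariantClass.MISSENSE, 1, wt, mt, 0.5, 20, 5.0)
    cands = enumerate_windows(v)
    assert len(cands) == 2
    assert all(c.windows == (1,) and c.mut_positions == frozenset({1}) for c in cands)


def test_frameshift_enumerates_novel_tail(frameshift_variant):
    cands = enumerate_windows(frameshift_variant)
    assert len(cands) == 15  # 8 nine-mers + 7 ten-mers intersecting [5,16]
    assert all(c.wt_seq is None for c in cands)


@pytest.mark.parametrize("seed", range(8))
def test_enumeration_matches_naive_scan_on_random_proteins(seed):
    rng = np.random.default_rng(seed)
    length = int(rng.integers(12, 61))
    wt = "".join(rng.choice(list(AA), size=length))
    pos = int(rng.integers(1, length + 1))
    new = rng.choice([a for a in AA if a != wt[pos - 1]])
    mt = wt[: pos - 1] + new + wt[pos:]
    v = VariantRecord("v", "G", VariantClass.MISSENSE, pos, wt, mt, 0.5, 20, 5.0)
    got = {c.mt_seq for c in enumerate_windows(v)}
    assert got == naive_windows(mt, {pos})


def test_identical_proteins_warn_and_yield_nothing():
    wt = "ARNDCQEGHILKMFPSTWYV"
    v = VariantRecord("v", "G", VariantClass.MISSENSE, 3, wt, wt, 0.5, 20, 5.0)
    with pytest.warns(UserWarning, match="identical"):
        assert enumerate_windows(v) == []


def test_noncanonical_residue_rejected():
    wt = "ARNDCQEGHILKMFPSTWYV"
    mt = wt[:2] + "U" + wt[3:]
    v = VariantRecord("v", "G", VariantClass.MISSENSE, 3, wt, mt, 0.5, 20, 5.0)
    with pytest.raises(ValueError, match="non-canonical"):
        enumerate_windows(v)


def test_inframe_insertion_windows_have_no_wt_counterpart():
    wt = "ARNDCQEGHILKMFPSTWYV"
    mt = wt[:5] + "KK" + wt[5:]
    v = VariantRecord("v", "G", VariantClass.INFRAME_INDEL, 6, wt, mt, 0.5, 20, 5.0)
    cands = enumerate_windows(v)
    assert cands
    assert all(c.wt_seq is None for c in cands)
    assert {c.mt_seq for c in cands} == naive_windows(mt, {6, 7})


# ---------------------------------------------------------------------------
# anchor filter


def _peptide(mut_positions, pid="p", seq="ARNDCQEGH"):
    return CandidatePeptide(
        peptide_id=pid,
        mt_seq=seq,
        wt_seq=None,
        mut_positions=frozenset(mut_positions),
        source_variant="v",
        vaf=0.3,
        read_count=20,
        tpm=10.0,
    )


def test_anchor_filter_removes_position_two_mutations():
    kept, log = filter_anchor([_peptide({2}), _peptide({1}), _peptide({5, 2})])
    assert [sorted(p.mut_positions) for p in kept] == [[1]]
    assert log.removed["anchor_position_2"] == 2


def test_anchor_filter_on_enumerated_windows_matches_offset_arithmetic(
    missense_variant,
):
    cands = enumerate_windows(missense_variant)
    kept, log = filter_anchor(cands)
    # the mutation lands on peptide position 2 exactly for windows starting
    # at protein_pos - 1, once per length
    assert log.removed["anchor_position_2"] == 2
    removed = {c.peptide_id for c in cands} - {c.peptide_id for c in kept}
    starts = {c.windows[0] for c in cands if c.peptide_id in removed}
    assert starts == {missense_variant.protein_pos - 1}


# ---------------------------------------------------------------------------
# expression filter


@pytest.mark.parametrize(
    "vaf,reads,tpm,expect_kept",
    [
        (0.0, 50, 100.0, False),  # VAF must be strictly positive
        (0.3, 10, 100.0, False),  # strict > on read counts
        (0.3, 11, 100.0, True),
        (0.3, 11, 2.0, False),  # log10(2) < 0.4
    ],
)
def test_expression_gates(vaf, reads, tpm, expect_kept):
    p = _peptide({1})
    p.vaf, p.read_count, p.tpm = vaf, reads, tpm
    kept, _ = filter_expression([p])
    assert bool(kept) == expect_kept


def test_tpm_gate_is_configurable():
    import math

    gate = TpmGate(threshold=0.4, transform=math.log, name="ln(TPM) > 0.4")
    p = _peptide({1})
    p.tpm = 2.0  # ln 2 = 0.69 passes, log10 2 = 0.30 fails
    assert gate(p.tpm)
    kept, _ = filter_expression([p], tpm_gate=gate)
    assert kept


# ---------------------------------------------------------------------------
# binding filter


def test_binding_cutoffs_inclusive():
    p1, p2 = _peptide({1}, "a", "ARNDCQEGH"), _peptide({1}, "b", "ARNDCQEGW")
    alleles = ["HLA-A*02:01"]
    aff = {("ARNDCQEGH", alleles[0]): 139.9, ("ARNDCQEGW", alleles[0]): 141.0}
    pr = {("ARNDCQEGH", alleles[0]): 0.5, ("ARNDCQEGW", alleles[0]): 0.5}
    kept, _ = filter_binding([p1, p2], aff, pr, alleles)
    assert [p.peptide_id for p in kept] == ["a"]


def test_binding_survives_via_any_allele_and_records_best():
    p = _peptide({1}, "a", "ARNDCQEGH")
    alleles = ["HLA-A*02:01", "HLA-B*07:02"]
    aff = {("ARNDCQEGH", alleles[0]): 100.0, ("ARNDCQEGH", alleles[1]): 120.0}
    pr = {("ARNDCQEGH", alleles[0]): 0.9, ("ARNDCQEGH", alleles[1]): 0.3}
    kept, _ = filter_binding([p], aff, pr, alleles)
    assert len(kept) == 1 and kept[0].allele == alleles[1]


def test_binding_missing_score_is_an_error():
    p = _peptide({1}, "a", "ARNDCQEGH")
    with pytest.raises(KeyError, match="ARNDCQEGH"):
        filter_binding([p], {}, {}, ["HLA-A*02:01"])


# ---------------------------------------------------------------------------
# invariants


def test_filters_are_order_independent(missense_variant):
    cands = enumerate_windows(missense_variant)
    # perturb expression of a few windows so the expression gate acts
    for i, c in enumerate(cands):
        if i % 3 == 0:
            c.read_count = 5
    alleles = ["HLA-A*02:01"]
    aff = {(c.mt_seq, alleles[0]): (80.0 if i % 2 else 500.0) for i, c in enumerate(cands)}
    pr = {(c.mt_seq, alleles[0]): 0.3 for c in cands}

    def ids(peps):
        return {p.peptide_id for p in peps}

    a, _ = filter_anchor(cands)
    a, _ = filter_expression(a)
    a, _ = filter_binding(a, aff, pr, alleles)

    b, _ = filter_binding(cands, aff, pr, alleles)
    b, _ = filter_anchor(b)
    b, _ = filter_expression(b)

    c_, _ = filter_expression(cands)
    c_, _ = filter_binding(c_, aff, pr, alleles)
    c_, _ = filter_anchor(c_)

    assert ids(a) == ids(b) == ids(c_)
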