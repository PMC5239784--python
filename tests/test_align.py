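"""Consecutive-run scoring, mismatch leniency, placement, indel repair."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vdjlineage import (LeniencyPolicy, best_ungapped_alignment,
                        correct_v_indels, score_match_pattern,
                        synthetic_germline_database)
from vdjlineage.align import _best_extent
from vdjlineage.germline import GermlineGene


def pattern_from_string(s: str) -> list:
    """Uppercase = match, lowercase = mismatch."""
    return [c.isupper() for c in s]


def oracle_score(pattern, budget: int) -> int:
    """Independent scorer: forgive the leftmost isolated mismatches.

    Walks the pattern element-wise, skipping forgiven positions so the
    flanking match runs fuse with zero contribution from the mismatch.
    """
    n = len(pattern)
    isolated = [i for i in range(n) if not pattern[i]
                and (i == 0 or pattern[i - 1])
                and (i == n - 1 or pattern[i + 1])]
    forgiven = set(isolated[:budget])
    score = fused = i = 0
    while i < n:
        if pattern[i]:
            fused += 1
            i += 1
        elif i in forgiven:
            i += 1
        else:
            j = i
            while j < n and not pattern[j] and j not in forgiven:
                j += 1
            score += fused * fused - (j - i) ** 2
            fused = 0
            i = j
    return score + fused * fused


class TestScoreMatchPattern:
    @pytest.mark.parametrize("string,budget,expected", [
        ("AGtTTcC", 0, 7),       # 2^2 - 1 + 2^2 - 1 + 1
        ("AGtTTcC", 1, 16),      # (2+0+2)^2 - 1 + 1: 5'-most forgiven first
        ("AGtTTcC", 2, 25),      # both isolated mismatches forgiven
        ("MMMM", 0, 16),
        ("mmm", 5, -9),          # runs of >=2 mismatches are never forgiven
        ("mMMM", 1, 9),          # forgiveness at the pattern terminus allowed
    ])
    def test_worked_examples(self, string, budget, expected):
        assert score_match_pattern(pattern_from_string(string), budget) == expected

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            score_match_pattern([])

    def test_ambiguous_positions_never_forgiven(self):
        pat = pattern_from_string("MMmMM")
        assert score_match_pattern(pat, 1) == 16
        assert score_match_pattern(pat, 1, forgivable=[1, 1, 0, 1, 1]) == 7

    @given(st.lists(st.booleans(), min_size=1, max_size=12),
           st.integers(min_value=0, max_value=3))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_oracle_and_monotone(self, pattern, budget):
        assert score_match_pattern(pattern, budget) == oracle_score(pattern, budget)
        assert (score_match_pattern(pattern, budget + 1)
                >= score_match_pattern(pattern, budget))


def oracle_extent(pattern, forgivable, budget_fn, min_overlap):
    """Independent greedy end-block trimming on plain Python lists."""
    nz = [i for i, p in enumerate(pattern) if p]
    if not nz:
        return None
    a, b = nz[0], nz[-1] + 1
    if b - a < min_overlap:
        return None

    def runs(sub):
        out = []
        i = 0
        while i < len(sub):
            j = i
            while j < len(sub) and sub[j] == sub[i]:
                j += 1
            out.append((sub[i], i, j))
            i = j
        return out

    def sc(x, y):
        pat = list(pattern[x:y])
        forg = list(forgivable[x:y])
        n = len(pat)
        iso = [i for i in range(n) if not pat[i] and forg[i]
               and (i == 0 or pat[i - 1]) and (i == n - 1 or pat[i + 1])]
        # oracle_score with a forgivability mask
        forgiven = set(iso[:budget_fn(n)])
        score = fused = i = 0
        while i < n:
            if pat[i]:
                fused += 1
                i += 1
            elif i in forgiven:
                i += 1
            else:
                j = i
                while j < n and not pat[j] and j not in forgiven:
                    j += 1
                score += fused * fused - (j - i) ** 2
                fused = 0
                i = j
        return score + fused * fused

    cur = sc(a, b)
    while True:
        rr = runs(pattern[a:b])
        if len(rr) < 3:
            break
        cands = []
        la = a + rr[2][1]
        if b - la >= min_overlap:
            cands.append((sc(la, b), b - la, 1, la, b))
        rb = a + rr[-3][2]
        if rb - a >= min_overlap:
            cands.append((sc(a, rb), rb - a, 0, a, rb))
        if not cands:
            break
        best = max(cands)
        if best[0] <= cur:
            break
        cur, a, b = best[0], best[3], best[4]
    return cur, a, b


@given(st.lists(st.booleans(), min_size=1, max_size=14),
       st.integers(min_value=0, max_value=2))
@settings(max_examples=300, deadline=None, derandomize=True)
def test_best_extent_matches_independent_reimplementation(pattern, budget):
    pat = np.array(pattern, dtype=bool)
    forg = np.ones(len(pattern), dtype=bool)
    pol = LeniencyPolicy(fixed=budget)
    got = _best_extent(pat, forg, pol.budget, min_overlap=1)
    expected = oracle_extent(pattern, [True] * len(pattern), pol.budget, 1)
    assert got == expected


def _gene(seq: str, name: str = "IGHD1-1*01") -> GermlineGene:
    return GermlineGene(name=name, segment_class="D", sequence=seq)


class TestBestUngappedAlignment:
    def test_identity_scores_length_squared(self):
        g = _gene("ACGTACGTAC")
        res = best_ungapped_alignment("ACGTACGTAC", g, LeniencyPolicy(fixed=0))
        assert res.score == 100
        assert res.n_mismatch == 0
        assert res.pattern.read_span == (1, 10)
        assert res.pattern.gene_span == (1, 10)

    def test_central_substitution_forgiven_at_same_placement(self):
        g = _gene("ACGTACGTAC")
        read = "ACGTGCGTAC"          # one substitution at position 5
        res0 = best_ungapped_alignment(read, g, LeniencyPolicy(fixed=0))
        res1 = best_ungapped_alignment(read, g, LeniencyPolicy(fixed=1))
        assert res0.pattern.read_span == res1.pattern.read_span == (1, 10)
        assert res0.score == 16 + 25 - 1
        assert res1.score == 81     # (4 + 0 + 5)^2
        assert res1.n_mismatch == 1

    def test_window_below_minimum_overlap_is_sentinel(self):
        g = _gene("ACGTACGT")
        res = best_ungapped_alignment("ACGTACGT", g, LeniencyPolicy(fixed=0),
                                      read_window=(1, 2), min_overlap=3)
        assert not res.aligned
        assert res.score == float("-inf")

    def test_equals_unpruned_offset_scan(self, db):
        """The match-count pruning and floor must not change the result."""
        import numpy as np
        from vdjlineage.align import encode, score_match_pattern
        rng = np.random.default_rng(7)
        pol = LeniencyPolicy(fixed=1)
        for trial in range(40):
            read = "".join(rng.choice(list("ACGT"), size=int(rng.integers(8, 31))))
            gene = _gene("".join(rng.choice(list("ACGT"),
                                            size=int(rng.integers(4, 13)))))
            fast = best_ungapped_alignment(read, gene, pol, min_overlap=3)
            # naive loop over every shift, same extent rule, no pruning
            r, g = encode(read), encode(gene.sequence)
            best = None
            for s in range(-(len(g) - 1), len(r)):
                a, b = max(0, s), min(len(r), len(g) + s)
                if b - a < 1:
                    continue
                pat = r[a:b] == g[a - s:b - s]
                ext = _best_extent(pat, r[a:b] != 4, pol.budget, 3)
                if ext is None:
                    continue
                sc, ea, eb = ext
                key = (sc, eb - ea, -s)
                if best is None or key > best[0]:
                    best = (key, a + ea, a + eb)
            if best is None:
                assert not fast.aligned
            else:
                assert fast.score == best[0][0]
                assert (fast.pattern.read_span ==
                        (best[1] + 1, best[2]))


class TestIndelCorrection:
    def test_planted_deletion_repaired(self, db):
        v = db.genes("V")[0]
        intact = v.sequence[-116:] + "CAGTACGTA"
        read = intact[:50] + intact[51:]          # drop one nt mid-framework
        pol = LeniencyPolicy(fraction=0.15)
        res = best_ungapped_alignment(read, v, pol,
                                      read_window=(1, len(read) - 9),
                                      min_overlap=10)
        fixed, log = correct_v_indels(read, res, v, pol)
        assert len(log) == 1
        assert log[0][1] == "ins"
        assert fixed == intact

    def test_clean_read_unchanged(self, db):
        v = db.genes("V")[0]
        read = v.sequence[-116:] + "CAGTACGTA"
        pol = LeniencyPolicy(fraction=0.15)
        res = best_ungapped_alignment(read, v, pol,
                                      read_window=(1, len(read) - 9),
                                      min_overlap=10)
        fixed, log = correct_v_indels(read, res, v, pol)
        assert fixed == read
        assert log == []

    def test_indel_in_cdr3_region_not_touched(self, db):
        v = db.genes("V")[0]
        # V segment intact; an extra nt after the 104Cys anchor only
        read = v.sequence[-116:] + "CAGTACGTA"
        anchor_read = len(read) - 9 - (len(v.sequence) - v.anchor_pos + 1) + 1
        mangled = read[:anchor_read + 4] + "G" + read[anchor_read + 4:]
        pol = LeniencyPolicy(fraction=0.15)
        res = best_ungapped_alignment(mangled, v, pol,
                                      read_window=(1, len(mangled) - 9),
                                      min_overlap=10)
        fixed, log = correct_v_indels(mangled, res, v, pol)
        assert fixed == mangled
        assert log == []
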