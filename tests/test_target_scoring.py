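"""Seed-site discovery and nearest-neighbor energy scoring."""

import numpy as np
import pytest

from tarsnp.reference_io import AlleleWindow, MiRnaRecord
from tarsnp.target_scoring import (
    AU_END_PENALTY,
    DUPLEX_INIT,
    STACK_TABLE,
    EnergyModel,
    SeedRules,
    SeedSite,
    TableScoreProvider,
    accessibility_energy,
    duplex_energy,
    find_seed_sites,
    score_sequence,
    score_site,
)

RNA_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
GU = {("G", "U"), ("U", "G")}
WEAK = {("A", "U"), ("U", "A")} | GU


def window(seq, snp_offset=0):
    return AlleleWindow(snp_id="rs", gene_id="g", allele="wild",
                        sequence=seq, snp_offset=snp_offset)


def mirna(seq, name="mir"):
    return MiRnaRecord(mirna_id=name, sequence=seq)


def perfect_site_dna(m, seed_len):
    """Sense DNA complementary (antiparallel) to miRNA positions 2..seed_len+1."""
    return "".join(
        RNA_WC[m.sequence[seed_len - k]] for k in range(seed_len)
    ).replace("U", "T")


def brute_force_sites(window_dna, m, rules=None):
    """Independent enumerator: test every (offset, seed length) directly."""
    rules = rules or SeedRules()
    w = window_dna.upper().replace("T", "U")
    found = []
    for ws in range(len(w)):
        for s in sorted(rules.seed_lengths):
            if len(m.sequence) < s + 1 or ws + s > len(w):
                continue
            gu = mm = 0
            for k in range(s):
                pair = (m.sequence[s - k], w[ws + k])
                if RNA_WC[pair[0]] == pair[1]:
                    continue
                if pair in GU:
                    gu += 1
                else:
                    mm += 1
            if (
                gu <= rules.gu_allowance.get(s, 0)
                and mm <= rules.mismatch_allowance.get(s, 0)
                and gu + mm <= rules.max_imperfections
            ):
                found.append((ws, s, gu, mm))
    return sorted(found)


def random_seq(rng, alphabet, n):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


class TestFindSeedSites:
    def test_planted_perfect_seed_found(self):
        m = mirna("ACGUACGUACGUACGUACGUAC")
        w = "A" * 20 + perfect_site_dna(m, 7) + "A" * 20
        sites = find_seed_sites(window(w), m)
        assert any(s.seed_len >= 7 and s.mismatch_count == 0 for s in sites)

    def test_no_complementarity_no_sites(self):
        assert find_seed_sites(window("A" * 30), mirna("A" * 22)) == []

    def test_order_is_ascending_window_start(self):
        m = mirna("ACGUACGUACGUACGUACGUAC")
        site = perfect_site_dna(m, 7)
        w = "A" * 5 + site + "AAA" + site + "A" * 5
        starts = [s.window_start for s in find_seed_sites(window(w), m)]
        assert starts == sorted(starts)

    @pytest.mark.parametrize("wlen", [12, 20, 61])
    def test_matches_brute_force_enumerator(self, wlen):
        rng = np.random.default_rng(wlen)
        for _ in range(200):
            w = random_seq(rng, "ACGT", wlen)
            m = mirna(random_seq(rng, "ACGU", 22))
            got = [
                (s.window_start, s.seed_len, s.gu_count, s.mismatch_count)
                for s in find_seed_sites(window(w), m)
            ]
            assert sorted(got) == brute_force_sites(w, m)


class TestDuplexEnergy:
    def test_two_bp_gc_duplex_is_init_plus_one_stack(self):
        # 5'GC3' paired with 5'GC3' antiparallel: one GC/CG stack
        expected = DUPLEX_INIT + STACK_TABLE[(("G", "C"), ("C", "G"))]
        assert duplex_energy("GC", "GC") == pytest.approx(expected)
        assert duplex_energy("GC", "GC") == pytest.approx(0.70)

    def test_deterministic(self):
        assert duplex_energy("GCAUG", "CAUGC") == duplex_energy("GCAUG", "CAUGC")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            duplex_energy("GC", "GCA")

    def test_perfect_duplexes_match_positional_resummation(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(2, 15))
            top = random_seq(rng, "ACGU", n)
            bottom = "".join(RNA_WC[b] for b in top)[::-1]
            pairs = [(top[i], bottom[n - 1 - i]) for i in range(n)]
            expected = DUPLEX_INIT + sum(
                STACK_TABLE[(pairs[i], pairs[i + 1])] for i in range(n - 1)
            )
            expected += AU_END_PENALTY * sum(1 for end in (pairs[0], pairs[-1]) if end in WEAK)
            assert duplex_energy(top, bottom) == pytest.approx(expected)

    def test_mismatch_to_watson_crick_never_raises_energy(self):
        """Strengthening complementarity is monotone in the energy model.

        True mismatches only: a G:U wobble is a valid pair, and under the
        Turner stacks a wobble can bind tighter than the A-U pair it would
        become, so wobbles are excluded from the draw.
        """
        gu_partner = {"G": "U", "U": "G"}
        rng = np.random.default_rng(7)
        for _ in range(500):
            n = int(rng.integers(4, 12))
            top = random_seq(rng, "ACGU", n)
            bottom = list("".join(RNA_WC[b] for b in top)[::-1])
            i = int(rng.integers(0, n))  # top position i pairs bottom n-1-i
            wc = bottom[n - 1 - i]
            banned = {wc, gu_partner.get(top[i], "")}
            choices = sorted(set("ACGU") - banned)
            mismatch = choices[int(rng.integers(0, len(choices)))]
            bottom[n - 1 - i] = mismatch
            e_mm = duplex_energy(top, "".join(bottom))
            bottom[n - 1 - i] = wc
            e_wc = duplex_energy(top, "".join(bottom))
            assert e_wc <= e_mm + 1e-12


class TestAccessibility:
    def test_disabled_is_zero_for_any_input(self):
        site = SeedSite(window_start=2, seed_len=8, gu_count=0, mismatch_count=0)
        assert accessibility_energy("GCGCGCGCAAAAGCGCGCGC", site, EnergyModel()) == 0.0

    def test_unstructured_window_costs_nothing(self):
        site = SeedSite(window_start=2, seed_len=8, gu_count=0, mismatch_count=0)
        model = EnergyModel(accessibility_enabled=True)
        assert accessibility_energy("A" * 20, site, model) == pytest.approx(0.0)

    def test_hairpin_costs_more_than_unstructured_control(self):
        site = SeedSite(window_start=2, seed_len=8, gu_count=0, mismatch_count=0)
        model = EnergyModel(accessibility_enabled=True)
        hairpin = accessibility_energy("GCGCGCGCAAAAGCGCGCGC", site, model)
        control = accessibility_energy("GCGCGCGC" + "A" * 12, site, model)
        assert hairpin > control


class TestScoreSequence:
    def test_absent_when_no_seed_site(self):
        assert score_sequence(window("A" * 61), mirna("A" * 22)) is None

    def test_single_planted_site_is_the_reported_score(self):
        m = mirna("ACGUACGUACGUACGUACGUAC")
        w = window("A" * 20 + perfect_site_dna(m, 7) + "A" * 20)
        result = score_sequence(w, m)
        per_site = [score_site(w, m, s) for s in find_seed_sites(w, m)]
        assert result.score == min(sc.score for sc in per_site)
        assert result.score == pytest.approx(result.dG_duplex + result.dG_open)

    def test_minimum_score_site_selected_among_planted_pair(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            m = mirna(random_seq(rng, "ACGU", 22))
            w = window(
                "A" * 6 + perfect_site_dna(m, 7) + "AAAA" + perfect_site_dna(m, 8) + "A" * 6
            )
            sites = find_seed_sites(w, m)
            assert len(sites) >= 2
            result = score_sequence(w, m)
            scores = [score_site(w, m, s).score for s in sites]
            assert result.score == min(scores)

    def test_pure_function(self):
        m = mirna("ACGUACGUACGUACGUACGUAC")
        w = window("A" * 20 + perfect_site_dna(m, 7) + "A" * 20)
        assert score_sequence(w, m) == score_sequence(w, m)


class TestTableProvider:
    def test_round_trip_and_absent_handling(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text(
            "snp_id\tmirna_id\tallele\tscore\n"
            "rs1\tmirA\twild\t-8.86\n"
            "rs1\tmirA\tvariant\t\n"
        )
        provider = TableScoreProvider.from_tsv(str(path))
        assert provider.score("rs1", "mirA", "wild") == -8.86
        assert provider.score("rs1", "mirA", "variant") is None
        assert provider.score("rs2", "mirA", "wild") is None
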