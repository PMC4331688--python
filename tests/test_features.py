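"""Feature extractors and BIO label handling."""

import pytest
from hypothesis import given, strategies as st

from chemner.corpus import EntityMention
from chemner.features import (
    ClusterMap,
    FeatureConfig,
    Gazetteer,
    assemble_features,
    cluster_feature,
    decode_bio,
    gazetteer_features,
    label_bio,
    soundex,
    token_features,
    word_class,
)
from chemner.tokenization import Token, tokenize

words = st.text(alphabet=st.characters(min_codepoint=ord("a"),
                                       max_codepoint=ord("z")),
                min_size=1, max_size=12)


class TestSoundex:
    @pytest.mark.parametrize(
        "word,digits,code",
        [
            ("carbon", 3, "C615"),
            ("carbonate", 3, "C615"),
            ("carbonic", 3, "C615"),
            ("carbonyl", 3, "C615"),
            ("carbonate", 7, "C6153"),
            ("A", 7, "A"),
            ("2,4", 7, "#"),
            ("Pfizer", 7, "P26"),   # second letter shares the first's code
            ("Ashcraft", 7, "A2613"),  # H transparent between equal codes
            ("Tymczak", 7, "T522"),
        ],
    )
    def test_known_codes(self, word, digits, code):
        assert soundex(word, digits) == code

    def test_max_digits_validation(self):
        with pytest.raises(ValueError):
            soundex("carbon", 0)

    @given(words)
    def test_case_insensitive(self, w):
        assert soundex(w) == soundex(w.upper())

    @given(words, st.integers(min_value=1, max_value=10))
    def test_output_pattern(self, w, d):
        code = soundex(w, d)
        assert code == "#" or (
            code[0].isalpha()
            and code[0].isupper()
            and code[1:].isdigit() is (len(code) > 1)
            and len(code) - 1 <= d
        )

    @given(words)
    def test_hw_deletion_preserves_code(self, w):
        """H and W beyond the first letter are transparent: deleting them
        never changes the code (vowels, by contrast, break digit runs)."""
        stripped = w[0] + "".join(ch for ch in w[1:] if ch not in "hw")
        assert soundex(w, 100) == soundex(stripped, 100)

    @given(words)
    def test_longer_budget_extends_shorter_code(self, w):
        """Codes at smaller digit budgets are prefixes of larger-budget codes."""
        assert soundex(w, 100).startswith(soundex(w, 3))


class TestWordClass:
    @pytest.mark.parametrize(
        "word,full,brief",
        [("Ca(2+)", "Aax0xx", "Aax0x"), ("carbon", "aaaaaa", "a"), ("", "", "")],
    )
    def test_mapping_and_collapse(self, word, full, brief):
        assert word_class(word) == (full, brief)

    @given(st.text(max_size=20))
    def test_brief_idempotent_under_collapse(self, w):
        _, brief = word_class(w)
        _, twice = word_class(brief)
        # collapsing an already-collapsed pattern of A/a/0/x classes is a no-op
        assert all(a != b for a, b in zip(brief, brief[1:]))
        assert len(twice) <= len(brief)


class TestTokenFeatures:
    def test_formula_token_predicates(self):
        feats = token_features("CO2")
        assert {"formula_like", "has_digit", "all_caps", "ends_digit",
                "ngram2=CO", "ngram2=O2"} <= feats

    def test_word_token_predicates(self):
        feats = token_features("Methanol")
        assert "formula_like" not in feats  # "th" is two consecutive lowercase
        assert "init_cap" in feats and "mixed_case" in feats

    def test_sentence_start_flag(self):
        feats = token_features("carbon", is_sentence_start=True)
        assert {"sentence_start", "lower=carbon", "word=carbon"} <= feats
        assert "sentence_start" not in token_features("carbon")

    def test_deterministic(self):
        assert token_features("1,2-diol") == token_features("1,2-diol")

    def test_soundex_and_nlp_toggles(self):
        feats = token_features("carbon", use_soundex=False, use_nlp=False)
        assert not any(f.startswith(("soundex=", "wc=", "wcb=")) for f in feats)
        feats = token_features("carbon", soundex_digits=3)
        assert "soundex=C615" in feats


class TestClusterFeature:
    def test_paper_style_lookup(self):
        cm = ClusterMap({"Tetralinoleoyl": 8}, 20)
        assert cluster_feature("Tetralinoleoyl", cm) == "cluster=8"

    def test_absent_term_sets_no_feature(self):
        assert cluster_feature("absent", ClusterMap({"x": 0}, 5)) is None
        assert cluster_feature("anything", ClusterMap({}, 5)) is None

    def test_lowercase_fallback(self):
        cm = ClusterMap({"calcium": 3}, 5)
        assert cluster_feature("Calcium", cm) == "cluster=3"

    def test_cluster_ids_validated(self):
        with pytest.raises(ValueError):
            ClusterMap({"x": 9}, 5)

    def test_tsv_round_trip(self, tmp_path):
        cm = ClusterMap({"a": 1, "b": 4}, 5)
        cm.to_tsv(tmp_path / "cm.tsv")
        back = ClusterMap.from_tsv(tmp_path / "cm.tsv", k=5)
        assert back.mapping == cm.mapping


class TestGazetteerFeatures:
    def _toks(self, *surfaces):
        out, pos = [], 0
        for s in surfaces:
            out.append(Token(s, pos, pos + len(s)))
            pos += len(s) + 1
        return out

    def test_token_and_full_entry_match(self):
        gaz = Gazetteer("main", frozenset({("acetic", "acid")}))
        toks = self._toks("acetic", "acid")
        assert gazetteer_features(toks, 0, [gaz]) == {"in_main", "in_main_full"}
        assert gazetteer_features(toks, 1, [gaz]) == {"in_main", "in_main_full"}

    def test_partial_sequence_no_full_match(self):
        gaz = Gazetteer("main", frozenset({("acetic", "acid")}))
        toks = self._toks("acetic", "ester")
        assert gazetteer_features(toks, 0, [gaz]) == {"in_main"}

    def test_unknown_token_empty(self):
        gaz = Gazetteer("main", frozenset({("carbon",)}))
        assert gazetteer_features(self._toks("xyzzy"), 0, [gaz]) == set()

    def test_suffix_mode(self):
        gaz = Gazetteer("affix", frozenset({("yl",)}), match_mode="suffix")
        assert gazetteer_features(self._toks("methyl"), 0, [gaz]) == {
            "suffix_affix"
        }

    def test_boost_gazetteer_emits_boost(self):
        gaz = Gazetteer("boosted", frozenset({("co2",)}), boost=True)
        feats = gazetteer_features(self._toks("CO2"), 0, [gaz])
        assert "boost" in feats

    def test_loading_from_file(self, tmp_path):
        path = tmp_path / "gaz.txt"
        path.write_text("acetic acid\ncarbon\n", encoding="utf-8")
        gaz = Gazetteer.from_file(path, "main")
        assert ("acetic", "acid") in gaz.entries
        with pytest.raises(ValueError, match="no terms"):
            empty = tmp_path / "empty.txt"
            empty.write_text("\n")
            Gazetteer.from_file(empty)


class TestAssembleFeatures:
    def test_window_rekeys_neighbors(self):
        toks = tokenize("sodium chloride dissolved")
        sets = assemble_features(toks)
        middle = sets[1]
        assert "word[-1]=sodium" in middle
        assert "word[+1]=dissolved" in middle
        assert "word[-2]=sodium" not in middle  # out of range at index 1

    def test_single_token_sentence_has_no_offset_keys(self):
        [s] = assemble_features(tokenize("carbon"))
        assert not any("[" in k and "]" in k for k in s if not k.startswith("wc"))

    def test_window_zero_family_stays_local(self):
        toks = tokenize("sodium chloride")
        cfg = FeatureConfig()
        assert cfg.windows["soundex"] == 0
        sets = assemble_features(toks, cfg)
        assert not any(k.startswith("soundex[") for s in sets for k in s)

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="unknown feature config"):
            FeatureConfig.from_dict({"use_sound": True})


class TestBioLabels:
    def _toks(self, text):
        return tokenize(text)

    def test_multiword_mention_labels(self):
        toks = self._toks("acetic acid reacts")
        labels, bad = label_bio(toks, [EntityMention("d", "A", 0, 11, "acetic acid")])
        assert labels == ["B", "I", "O"] and bad == 0

    def test_no_mentions_all_outside(self):
        labels, bad = label_bio(self._toks("no chemicals here"), [])
        assert labels == ["O", "O", "O"] and bad == 0

    def test_misaligned_mention_skipped_and_counted(self):
        toks = self._toks("water CO2 rose")
        labels, bad = label_bio(toks, [EntityMention("d", "A", 6, 8, "CO")])
        assert labels == ["O", "O", "O"] and bad == 1

    def test_overlapping_gold_rejected(self):
        toks = self._toks("acetic acid reacts")
        with pytest.raises(ValueError, match="overlap"):
            label_bio(toks, [EntityMention("d", "A", 0, 11), EntityMention("d", "A", 7, 18)])

    def test_decode_runs_and_orphan_i(self):
        toks = self._toks("acetic acid reacts")
        text = "acetic acid reacts"
        [m] = decode_bio(toks, ["B", "I", "O"], "d", "A", text)
        assert (m.start, m.end, m.text) == (0, 11, "acetic acid")
        [m2] = decode_bio(toks, ["O", "I", "O"], "d", "A", text)
        assert (m2.start, m2.end) == (7, 11)  # I-as-B
        assert decode_bio(toks, ["O", "O", "O"], "d", "A", text) == []

    def test_decode_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            decode_bio(self._toks("a b"), ["B"])

    @given(st.data())
    def test_round_trip_on_synthetic_sentences(self, data):
        """decode(label(gold)) reproduces any token-aligned gold span set."""
        n_words = data.draw(st.integers(min_value=1, max_value=8))
        surfaces = [
            data.draw(words := st.sampled_from(
                ["carbon", "CO2", "flux", "ethanol", "rose", "H2O", "assay"]
            ))
            for _ in range(n_words)
        ]
        text = " ".join(surfaces)
        toks = tokenize(text)
        # choose a random subset of non-adjacent token runs as gold
        gold = []
        i = 0
        while i < len(toks):
            if data.draw(st.booleans()):
                j = min(len(toks) - 1, i + data.draw(st.integers(0, 2)))
                gold.append(
                    EntityMention("d", "A", toks[i].start, toks[j].end,
                                  text[toks[i].start : toks[j].end])
                )
                i = j + 2
            else:
                i += 1
        labels, bad = label_bio(toks, gold)
        assert bad == 0
        decoded = decode_bio(toks, labels, "d", "A", text)
        assert [(m.start, m.end) for m in decoded] == [
            (m.start, m.end) for m in gold
        ]
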