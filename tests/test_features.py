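"""Feature extractors: the five families and their printed worked examples."""

from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from bioner.corpus import Sentence, Token
from bioner.features import (
    FeatureConfig,
    affix_features,
    char_ngram_features,
    conjunction_features,
    dependency_features,
    extract_features,
    linguistic_features,
    orthographic_features,
    window_features,
    word_shape,
    write_feature_file,
)
from bioner.tokenization import tokenize

from .conftest import make_sentence


def _example_sentence() -> Sentence:
    """The worked-example sentence with lemma/POS attributes attached."""
    text = "Pharmacologic aspects of neonatal hyperbilirubinemia."
    toks = tokenize(text)
    attrs = {
        "Pharmacologic": ("pharmacologic", "JJ"),
        "aspects": ("aspect", "NNS"),
        "of": ("of", "IN"),
        "neonatal": ("neonatal", "JJ"),
        "hyperbilirubinemia": ("hyperbilirubinemia", "NN"),
        ".": (".", "."),
    }
    rich = [
        Token(t.text, t.start, t.end, lemma=attrs[t.text][0], pos=attrs[t.text][1])
        for t in toks
    ]
    return Sentence(id="ex", text=text, tokens=rich)


class TestOrthographic:
    @pytest.mark.parametrize(
        "token,expected",
        [
            ("MyoD", {"ORT=InitCap", "ORT=MixedCase"}),
            ("123", {"ORT=AllDigits", "ORT=ContainsDigit"}),
            ("-", {"ORT=SingleChar", "ORT=ContainsHyphen"}),
            ("kinase", {"ORT=AllLower"}),
            ("DNA", {"ORT=InitCap", "ORT=AllCaps"}),
            ("alpha", {"ORT=AllLower", "ORT=GreekLetter"}),
            ("II", {"ORT=InitCap", "ORT=AllCaps", "ORT=RomanNumeral"}),
            ("p53/IV", {"ORT=ContainsDigit", "ORT=ContainsSlash", "ORT=MixedCase"}),
        ],
    )
    def test_canonical_patterns(self, token, expected):
        assert set(orthographic_features(token)) == expected

    def test_pattern_subset_selection(self):
        only = orthographic_features("MyoD", patterns=("InitCap",))
        assert only == ["ORT=InitCap"]


class TestAffixesAndNgrams:
    @pytest.mark.parametrize(
        "token,lengths,expected",
        [
            ("kinase", (3,), {"PREFIX=kin", "SUFFIX=ase"}),
            ("ab", (3,), set()),
            ("genome", (2, 3), {"PREFIX=ge", "PREFIX=gen", "SUFFIX=me", "SUFFIX=ome"}),
        ],
    )
    def test_affixes(self, token, lengths, expected):
        assert set(affix_features(token, lengths)) == expected

    @pytest.mark.parametrize(
        "token,sizes,expected",
        [
            ("abcd", (2,), {"NGRAM=ab", "NGRAM=bc", "NGRAM=cd"}),
            ("ase", (3,), {"NGRAM=ase"}),
            ("p53", (2, 3), {"NGRAM=p5", "NGRAM=53", "NGRAM=p53"}),
        ],
    )
    def test_ngrams(self, token, sizes, expected):
        assert set(char_ngram_features(token, sizes)) == expected

    def test_ngram_size_one_rejected(self):
        with pytest.raises(ValueError):
            char_ngram_features("abc", (1,))


class TestWordShapes:
    @pytest.mark.parametrize(
        "token,stype,expected",
        [
            ("Abc1234", "I", "Abc*"),
            ("Abc:1234", "II", "Aaa#1111"),
            ("Abc:1234", "III", "a#1"),
            ("IL-2", "I", "IL-*"),
            ("IL-2", "II", "AA#1"),
            ("IL-2", "III", "a#1"),
        ],
    )
    def test_printed_transformations(self, token, stype, expected):
        assert word_shape(token, stype) == expected

    @given(st.text(alphabet=st.characters(codec="ascii", exclude_categories=["Cc", "Zs"]), min_size=1, max_size=20))
    def test_shapes_agree_with_character_class_oracle(self, text):
        def cls(c):
            return "A" if c.isupper() else "a" if c.islower() else "1" if c.isdigit() else "#"

        # type II is the exact per-character class map
        assert word_shape(text, "II") == "".join(cls(c) for c in text)
        assert len(word_shape(text, "II")) == len(text)
        # type I only touches digits
        assert len(word_shape(text, "I")) <= len(text)
        # type III collapses runs of the coarse classes (letters pooled)
        def coarse(c):
            return "a" if c.isalpha() else "1" if c.isdigit() else "#"

        expected = []
        for c in text:
            k = coarse(c)
            if not expected or expected[-1] != k:
                expected.append(k)
        assert word_shape(text, "III") == "".join(expected)


class TestLinguisticAndDependency:
    def test_linguistic_emission(self):
        tok = Token("binds", 0, 5, lemma="bind", pos="VBZ")
        assert set(linguistic_features(tok)) == {"TOKEN=binds", "LEMMA=bind", "POS=VBZ"}

    def test_chunk_tag_emitted(self):
        tok = Token("factor", 0, 6, chunk="B-NP")
        assert "CHUNK=B-NP" in linguistic_features(tok)

    def test_bare_token_only(self):
        tok = Token("x", 0, 1)
        assert linguistic_features(tok) == ["TOKEN=x"]

    def test_subject_object_arcs(self):
        text = "BRCA1 activates p53"
        toks = tokenize(text)
        rich = [
            Token(toks[0].text, toks[0].start, toks[0].end, lemma="BRCA1", pos="NN"),
            Token(toks[1].text, toks[1].start, toks[1].end, lemma="activate", pos="VBZ"),
            Token(toks[2].text, toks[2].start, toks[2].end, lemma="p53", pos="NN"),
        ]
        sent = Sentence(id="s", text=text, tokens=rich,
                        dependencies=[(1, 0, "SUBJ"), (1, 2, "OBJ")])
        feats = dependency_features(sent)
        assert feats[0] == ["DEP_SUBJ_OF=activate"]
        assert feats[2] == ["DEP_OBJ_OF=activate"]

    def test_modifier_arcs_both_directions(self):
        text = "neonatal hyperbilirubinemia"
        toks = tokenize(text)
        rich = [
            Token(toks[0].text, toks[0].start, toks[0].end, lemma="neonatal", pos="JJ"),
            Token(toks[1].text, toks[1].start, toks[1].end,
                  lemma="hyperbilirubinemia", pos="NN"),
        ]
        sent = Sentence(id="s", text=text, tokens=rich, dependencies=[(1, 0, "NMOD")])
        feats = dependency_features(sent)
        assert feats[0] == ["DEP_MODIFIES=hyperbilirubinemia"]
        assert feats[1] == ["DEP_MODIFIER=neonatal"]

    def test_no_arcs_no_features(self):
        sent = make_sentence("a b c")
        assert dependency_features(sent) == [[], [], []]

    def test_out_of_range_arc_is_error(self):
        sent = make_sentence("a b")
        sent.dependencies.append((0, 5, "SUBJ"))
        with pytest.raises(ValueError, match="out of range"):
            dependency_features(sent)


class TestContext:
    def test_window_copies_neighbour_tokens(self):
        sent = _example_sentence()
        cfg = FeatureConfig(
            conjunctions=False, windows=True, window_range=(-1, 1),
            window_sources=("TOKEN",),
        )
        vectors = extract_features(sent, cfg)
        neonatal = vectors[3]
        assert "TOKEN=of@-1" in neonatal
        assert "TOKEN=hyperbilirubinemia@1" in neonatal

    def test_window_zero_range_is_noop(self):
        sent = _example_sentence()
        base = extract_features(sent, FeatureConfig(conjunctions=False))
        windowed = extract_features(
            sent,
            FeatureConfig(conjunctions=False, windows=True, window_range=(0, 0)),
        )
        assert [v.features for v in base] == [v.features for v in windowed]

    def test_conjunction_printed_examples(self):
        """The symmetric (-1,1) spec conjoins only the two neighbours."""
        sent = _example_sentence()
        conj = conjunction_features(sent, [(-1, 1)], ["lemma", "pos"])
        neonatal = conj[3]
        assert "LEMMA=of@-1_&_LEMMA=hyperbilirubinemia@1" in neonatal
        assert "POS=IN@-1_&_POS=NN@1" in neonatal

    def test_conjunction_includes_zero_endpoint(self):
        sent = _example_sentence()
        conj = conjunction_features(sent, [(-1, 0), (0, 1)], ["lemma"])
        neonatal = conj[3]
        assert "LEMMA=of@-1_&_LEMMA=neonatal@0" in neonatal
        assert "LEMMA=neonatal@0_&_LEMMA=hyperbilirubinemia@1" in neonatal

    def test_conjunction_out_of_range_spec_emits_nothing(self):
        sent = _example_sentence()
        conj = conjunction_features(sent, [(-3, -1)], ["lemma"])
        assert conj[0] == []

    def test_conjunction_count_bound(self):
        sent = _example_sentence()
        specs = [(-3, -1), (-2, -1), (-1, 0), (-1, 1), (0, 1)]
        conj = conjunction_features(sent, specs, ["lemma", "pos"])
        for feats in conj:
            assert len(feats) <= len(specs) * 2


class TestExtraction:
    def test_pure_function_of_input(self):
        sent = _example_sentence()
        cfg = FeatureConfig()
        a = [list(v.features) for v in extract_features(sent, cfg)]
        b = [list(v.features) for v in extract_features(sent, cfg)]
        assert a == b

    def test_no_whitespace_in_features(self):
        sent = _example_sentence()
        for vec in extract_features(sent, FeatureConfig()):
            for f in vec.features:
                assert " " not in f and "\t" not in f

    @pytest.mark.parametrize(
        "family,prefixes",
        [
            ("orthographic", ("ORT=",)),
            ("prefix_suffix", ("PREFIX=", "SUFFIX=")),
            ("ngrams", ("NGRAM=",)),
            ("shape_i", ("SHAPE1=",)),
            ("shape_ii", ("SHAPE2=",)),
            ("shape_iii", ("SHAPE3=",)),
            ("pos", ("POS=",)),
        ],
    )
    def test_disabling_family_removes_exactly_that_family(self, family, prefixes):
        sent = _example_sentence()
        full_cfg = FeatureConfig(conjunctions=False)
        off_cfg = FeatureConfig(conjunctions=False, **{family: False})
        full = extract_features(sent, full_cfg)
        off = extract_features(sent, off_cfg)
        for vf, vo in zip(full, off):
            removed = set(vf.features) - set(vo.features)
            assert all(f.startswith(prefixes) for f in removed)
            assert set(vo.features) == {
                f for f in vf.features if not f.startswith(prefixes)
            }

    def test_all_families_disabled_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            FeatureConfig(
                token=False, lemma=False, pos=False, chunk=False,
                orthographic=False, prefix_suffix=False, ngrams=False,
                shape_i=False, shape_ii=False, shape_iii=False,
                dependency=False, lexicon=False, trigger_words=False,
                conjunctions=False, windows=False,
            )

    def test_feature_file_format(self, tmp_path):
        sent = make_sentence("a b", annotations=[(0, 0, "PRGE")])
        from bioner.corpus import encode_bio

        vecs = extract_features(sent, FeatureConfig.token_only())
        path = tmp_path / "feat.tsv"
        write_feature_file([sent], [vecs], [encode_bio(sent)], path)
        lines = path.read_text().splitlines()
        assert lines[0] == "a\tTOKEN=a\tB-PRGE"
        assert lines[1] == "b\tTOKEN=b\tO"
        assert lines[2] == ""
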