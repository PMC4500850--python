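"""Fingerprint codec, Tanimoto scoring, neighboring rules, n-ary pattern."""

import base64
import random

import pytest
from hypothesis import given, settings, strategies as st
from rdflib import RDF, Literal
from rdflib.namespace import XSD

from chemrdf.namespaces import DEFAULT_NAMESPACES
from chemrdf.similarity import (
    FINGERPRINT_BITS,
    Fingerprint,
    FingerprintDialectError,
    NeighborPair,
    SimilarityConfig,
    decode_cactvs_subskeys,
    encode_cactvs_subskeys,
    neighbor_pairs,
    similarity_triples,
    tanimoto,
)

SIO = DEFAULT_NAMESPACES.namespace("sio")
VOCAB = DEFAULT_NAMESPACES.namespace("vocab")
NBR = DEFAULT_NAMESPACES.namespace("nbr")
COMPOUND = DEFAULT_NAMESPACES.namespace("compound")

bitsets = st.frozensets(st.integers(min_value=0, max_value=FINGERPRINT_BITS - 1),
                        max_size=FINGERPRINT_BITS)


class TestCodec:
    def test_declared_length_must_be_881(self):
        payload = (880).to_bytes(4, "big") + bytes(111)
        with pytest.raises(FingerprintDialectError):
            decode_cactvs_subskeys(base64.b64encode(payload).decode())

    def test_all_zero_payload_is_empty_bitset(self):
        payload = (881).to_bytes(4, "big") + bytes(111)
        fp = decode_cactvs_subskeys(base64.b64encode(payload).decode())
        assert fp.bits == frozenset() and fp.length == 881

    def test_msb_first_packing(self):
        body = bytearray(111)
        body[0] = 0x80          # bit 0
        body[1] = 0x01          # bit 15
        payload = (881).to_bytes(4, "big") + bytes(body)
        fp = decode_cactvs_subskeys(base64.b64encode(payload).decode())
        assert fp.bits == frozenset({0, 15})

    def test_non_base64_rejected(self):
        with pytest.raises(ValueError):
            decode_cactvs_subskeys("!!! not base64 !!!")

    def test_short_payload_rejected(self):
        with pytest.raises(ValueError):
            decode_cactvs_subskeys(base64.b64encode(b"\x00\x00").decode())

    @given(bitsets)
    @settings(max_examples=100, deadline=None)
    def test_encode_decode_round_trip(self, bits):
        fp = Fingerprint(bits)
        assert decode_cactvs_subskeys(encode_cactvs_subskeys(fp)) == fp


def tanimoto_oracle(a: frozenset, b: frozenset) -> float:
    """Brute-force set algebra over every bit position."""
    inter = sum(1 for i in range(FINGERPRINT_BITS) if i in a and i in b)
    union = sum(1 for i in range(FINGERPRINT_BITS) if i in a or i in b)
    return inter / union if union else 0.0


class TestTanimoto:
    def test_identity_is_one(self):
        fp = Fingerprint(frozenset({1, 5, 880}))
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto(Fingerprint(frozenset({1})), Fingerprint(frozenset({2}))) == 0.0

    def test_simple_overlap(self):
        a = Fingerprint(frozenset({1, 2, 3}))
        b = Fingerprint(frozenset({2, 3, 4}))
        assert tanimoto(a, b) == 0.5

    def test_both_empty_defined_zero(self):
        empty = Fingerprint(frozenset())
        assert tanimoto(empty, empty) == 0.0

    def test_against_brute_force_oracle_1000_pairs(self):
        rng = random.Random(20150714)
        for _ in range(1000):
            a = frozenset(rng.sample(range(FINGERPRINT_BITS), rng.randint(0, 400)))
            b = frozenset(rng.sample(range(FINGERPRINT_BITS), rng.randint(0, 400)))
            assert tanimoto(Fingerprint(a), Fingerprint(b)) == tanimoto_oracle(a, b)

    @given(bitsets, bitsets)
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_unit_range(self, a, b):
        fa, fb = Fingerprint(a), Fingerprint(b)
        s = tanimoto(fa, fb)
        assert s == tanimoto(fb, fa)
        assert 0.0 <= s <= 1.0
        if a and a == b:
            assert s == 1.0


def _fp(bits) -> Fingerprint:
    return Fingerprint(frozenset(bits))


class TestNeighborRules:
    def test_2d_threshold_is_inclusive(self):
        fps = {
            1: _fp(range(9)),
            2: _fp(range(10)),                       # T(1,2) = 9/10 = 0.90
            3: _fp(list(range(89)) + list(range(100, 111))),  # T(3,4) = 0.89
            4: _fp(range(89)),
        }
        pairs = neighbor_pairs(fps)
        kinds = {(p.cid_a, p.cid_b) for p in pairs}
        assert (1, 2) in kinds and (3, 4) not in kinds

    def test_threshold_monotonicity(self):
        rng = random.Random(3)
        fps = {}
        base = rng.sample(range(FINGERPRINT_BITS), 120)
        for cid in range(1, 12):
            variant = set(base)
            for pos in rng.sample(range(FINGERPRINT_BITS), rng.randint(0, 40)):
                variant.symmetric_difference_update({pos})
            fps[cid] = _fp(variant)
        previous = None
        for threshold in (0.5, 0.7, 0.9, 0.95, 1.0):
            config = SimilarityConfig(tanimoto_2d_threshold=threshold)
            current = {(p.cid_a, p.cid_b) for p in neighbor_pairs(fps, config=config)}
            if previous is not None:
                assert current <= previous
            previous = current

    def test_3d_rule_with_features(self):
        pairs = neighbor_pairs(
            {}, [(60823, 11330946, 0.88, 0.59)],
            features={60823: True, 11330946: True},
            known_cids={60823, 11330946},
        )
        (pair,) = pairs
        assert pair.kind == "3D" and pair.st == 0.88 and pair.ct == 0.59

    @pytest.mark.parametrize("st_score, ct_score, keep", [
        (0.80, 0.50, True),    # at both thresholds
        (0.79, 0.90, False),   # shape below
        (0.95, 0.49, False),   # feature below
    ])
    def test_3d_feature_thresholds(self, st_score, ct_score, keep):
        pairs = neighbor_pairs(
            {}, [(1, 2, st_score, ct_score)],
            features={1: True, 2: True}, known_cids={1, 2},
        )
        assert bool(pairs) is keep

    def test_3d_rule_without_features_uses_shape_only(self):
        rows = [(1, 2, 0.94, None), (3, 4, 0.92, None)]
        pairs = neighbor_pairs(
            {}, rows,
            features={1: False, 2: False, 3: False, 4: False},
            known_cids={1, 2, 3, 4},
        )
        assert [(p.cid_a, p.cid_b) for p in pairs] == [(1, 2)]

    def test_mixed_feature_case_emits_nothing(self):
        pairs = neighbor_pairs(
            {}, [(1, 2, 0.99, 0.99)],
            features={1: True, 2: False}, known_cids={1, 2},
        )
        assert pairs == []

    def test_unknown_cid_in_scores_rejected(self):
        with pytest.raises(KeyError):
            neighbor_pairs({}, [(1, 99, 0.9, 0.9)], known_cids={1, 2})

    def test_pairs_canonical_and_unique(self):
        rows = [(2, 1, 0.9, 0.9), (1, 2, 0.95, 0.95)]
        pairs = neighbor_pairs({}, rows, features={1: True, 2: True}, known_cids={1, 2})
        assert len(pairs) == 1 and pairs[0].cid_a == 1


class TestSimilarityTriples:
    def test_2d_pattern_matches_printed_block(self):
        pair = NeighborPair(60823, 10030610, "2D", tanimoto_2d=0.98)
        triples = set(similarity_triples(pair))
        assoc = NBR["CID60823_CID10030610_2DSimilarity"]
        score = NBR["CID60823_CID10030610_2DTanimotoScore"]
        assert (assoc, RDF.type, VOCAB["PC2D_structural_similarity"]) in triples
        assert (assoc, SIO["refers-to"], COMPOUND["CID60823"]) in triples
        assert (assoc, SIO["refers-to"], COMPOUND["CID10030610"]) in triples
        assert (assoc, SIO["has-measurement-value"], score) in triples
        assert (score, RDF.type, VOCAB["PC2D_Fingerprint_TanimotoScore"]) in triples
        assert (score, SIO["has-value"], Literal(0.98, datatype=XSD.double)) in triples

    def test_3d_pattern_has_two_score_nodes(self):
        pair = NeighborPair(60823, 11330946, "3D", st=0.88, ct=0.59)
        triples = set(similarity_triples(pair))
        shape = NBR["CID60823_CID11330946_3DShapeTanimotoScore"]
        feature = NBR["CID60823_CID11330946_3DFeatureTanimotoScore"]
        assert (shape, SIO["has-value"], Literal(0.88, datatype=XSD.double)) in triples
        assert (feature, SIO["has-value"], Literal(0.59, datatype=XSD.double)) in triples
        assert (shape, RDF.type, VOCAB["PC3D_Shape_TanimotoScore"]) in triples
        assert (feature, RDF.type, VOCAB["PC3D_Feature_TanimotoScore"]) in triples

    def test_score_provenance_link_flag(self):
        pair = NeighborPair(1, 2, "2D", tanimoto_2d=0.95)
        with_link = set(similarity_triples(pair, link_software=True))
        without = set(similarity_triples(pair, link_software=False))
        assert any(p == SIO["is-output-of"] for _, p, _ in with_link)
        assert not any(p == SIO["is-output-of"] for _, p, _ in without)

    def test_all_score_literals_are_doubles(self):
        pair = NeighborPair(1, 2, "3D", st=0.8123, ct=0.51)
        for _, p, o in similarity_triples(pair):
            if p == SIO["has-value"]:
                assert o.datatype == XSD.double
                float(o)  # lexical form parses
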