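"""Codec tests: codon categories, the reference keyboard, encode/decode,
homopolymer bounds, and DNA-record serialization."""

import string
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from musekit.errors import (
    EncodingError,
    DecodingError,
    InvalidCodonError,
    InvalidSequenceError,
    MalformedMessageError,
    MalformedRecordError,
    ValidationError,
)
from musekit.ikey import (
    ALL_CODONS,
    CodonCategory,
    ButtonKind,
    IKey,
    PBZ38_INTERIOR,
    build_reference_ikey,
    category_census,
    classify_codon,
    decode_dna,
    decode_message,
    encode_chars,
    encode_message,
    max_homopolymer_run,
    parse_ikey_record,
    randomize_ikey,
    serialize_ikey,
    variant_count,
)

SUPPORTED_CHARS = (
    string.ascii_lowercase + string.digits + " " + ".,:;!?'\"-&()/@#$%+=*_"
)


# ---------------------------------------------------------------------------
# Codon categories
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "codon, expected",
    [
        ("AGT", CodonCategory.CAT1),
        ("CTC", CodonCategory.CAT2),
        ("GTT", CodonCategory.CAT3),
        ("AAA", CodonCategory.CAT3),
        ("TAT", CodonCategory.CAT2),
    ],
)
def test_classify_codon(codon, expected):
    assert classify_codon(codon) is expected


@pytest.mark.parametrize("bad", ["AG", "AGTT", "AXT", "agt", ""])
def test_classify_codon_rejects_invalid(bad):
    with pytest.raises((InvalidCodonError, InvalidSequenceError)):
        classify_codon(bad)


def test_category_census_matches_brute_force_enumeration():
    """The (24, 12, 28) partition equals a direct triple loop over bases."""
    counts = {CodonCategory.CAT1: 0, CodonCategory.CAT2: 0, CodonCategory.CAT3: 0}
    for a, b, c in product("ACGT", repeat=3):
        if len({a, b, c}) == 3:
            counts[CodonCategory.CAT1] += 1
        elif a == c and b != a:
            counts[CodonCategory.CAT2] += 1
        else:
            counts[CodonCategory.CAT3] += 1
    assert category_census() == (
        counts[CodonCategory.CAT1],
        counts[CodonCategory.CAT2],
        counts[CodonCategory.CAT3],
    )
    assert category_census() == (24, 12, 28)
    assert sum(category_census()) == 64


def test_variant_count_reproduces_printed_magnitudes():
    within_categories = variant_count((24, 12, 28))
    assert f"{within_categories:.1e}" == "9.1e+61"
    unconstrained = variant_count(64)
    assert f"{unconstrained:.1e}" == "1.3e+89"
    assert variant_count((1, 1, 1)) == 1
    assert variant_count(()) == 1
    with pytest.raises(ValueError):
        variant_count((-1, 2))


# ---------------------------------------------------------------------------
# Reference keyboard
# ---------------------------------------------------------------------------

def test_reference_pinned_assignments(reference_ikey):
    assert reference_ikey.codon_of("1") == "AGC"
    assert reference_ikey.codon_of("0") == "CTG"
    assert reference_ikey.codon_of("v") == "GTT"
    assert reference_ikey.codon_of("k") == "TTC"
    assert reference_ikey.codon_of("space1") == "AGT"
    assert reference_ikey.codon_of("space2") == "CTA"
    function_homopolymers = {
        reference_ikey.codon_of(label) for label in ("start", "end", "shift", "forward")
    }
    assert function_homopolymers == {"AAA", "CCC", "GGG", "TTT"}


def test_reference_digits_are_cat1(reference_ikey):
    for digit in string.digits:
        assert reference_ikey.button_for_label(digit).category is CodonCategory.CAT1
        assert reference_ikey.button_for_label(digit).kind is ButtonKind.DIGIT


def test_reference_letters_fill_categories_by_frequency(reference_ikey):
    """Top-frequency letters get CAT1 codons, the next tier CAT2."""
    for ch in "earios":
        assert reference_ikey.button_for_label(ch).category is CodonCategory.CAT1
    for ch in "pmxzjq":
        assert reference_ikey.button_for_label(ch).category is CodonCategory.CAT2


def test_reference_serializes_to_printed_record(reference_ikey, constructs):
    record = serialize_ikey(reference_ikey)
    assert record.sequence == constructs["iKey-64"].sequence
    assert len(record.sequence) == 212
    assert record.sequence[:10] == "T" * 10 and record.sequence[-10:] == "T" * 10


def test_reference_matches_shipped_config_fixture(reference_ikey):
    from musekit.io import load_reference_ikey_config

    assert load_reference_ikey_config() == reference_ikey


def test_printed_record_interior_is_codon_permutation():
    triplets = [PBZ38_INTERIOR[i : i + 3] for i in range(0, 192, 3)]
    assert sorted(triplets) == sorted(ALL_CODONS)
    for pinned in ("AAA", "CCC", "GGG", "TTT", "AGT", "CTA", "AGC", "CTG", "GTT", "TTC"):
        assert pinned in triplets
    assert triplets[57] == "AGT" and triplets[58] == "CTA"


# ---------------------------------------------------------------------------
# Randomization
# ---------------------------------------------------------------------------

def test_randomize_is_deterministic_and_category_preserving(reference_ikey):
    for seed in range(100):
        shuffled = randomize_ikey(reference_ikey, seed)
        assert shuffled == randomize_ikey(reference_ikey, seed)
        assert shuffled.category_census() == (24, 12, 28)
        for old, new in zip(reference_ikey.buttons, shuffled.buttons):
            assert old.label == new.label and old.kind is new.kind
            assert old.category is new.category
    assert randomize_ikey(reference_ikey, 0) != randomize_ikey(reference_ikey, 1)


def test_randomize_rejects_non_ikey():
    with pytest.raises(ValidationError):
        randomize_ikey("not a keyboard", 0)


# ---------------------------------------------------------------------------
# Encoding / decoding
# ---------------------------------------------------------------------------

def test_printed_worked_encodings(reference_ikey):
    vk = encode_chars("VK", reference_ikey, shift_policy=False)
    assert str(vk) == "GTTTTC"
    assert max_homopolymer_run(str(vk)) == 4
    digits = encode_chars("110011", reference_ikey)
    assert str(digits) == "AGCAGCCTGCTGAGCAGC"
    assert max_homopolymer_run(str(digits)) == 2
    assert str(encode_chars("", reference_ikey)) == ""


def test_decode_inverts_printed_examples(reference_ikey):
    assert decode_dna("GTTTTC", reference_ikey) == "vk"
    assert decode_dna("AGCAGCCTGCTGAGCAGC", reference_ikey) == "110011"


def test_framed_message_structure(reference_ikey):
    framed = encode_message("", reference_ikey)
    assert len(framed) == 6 and framed.frame
    assert framed.dna[:3] == reference_ikey.codon_of("start")
    assert framed.dna[-3:] == reference_ikey.codon_of("end")
    text = "Massachusetts Institute Technology"
    encoded = encode_message(text, reference_ikey)
    # frame(2) + shift per capital(3) + characters(34, incl. 2 spaces)
    assert len(encoded) == 3 * (2 + 3 + len(text))
    assert decode_message(encoded, reference_ikey) == text


def test_encode_errors_name_character_and_position(reference_ikey):
    with pytest.raises(EncodingError, match=r"'~'.*position 2"):
        encode_chars("ab~c", reference_ikey)


def test_decode_errors(reference_ikey):
    with pytest.raises(DecodingError):
        decode_dna("AGTC", reference_ikey)  # not a codon multiple
    with pytest.raises(MalformedMessageError):
        decode_dna(reference_ikey.codon_of("shift"), reference_ikey)  # trailing shift
    with pytest.raises(MalformedMessageError):
        decode_dna(reference_ikey.codon_of("shift") * 2, reference_ikey)
    with pytest.raises(MalformedMessageError):
        decode_message(encode_chars("abc", reference_ikey), reference_ikey)


@settings(max_examples=150, deadline=None)
@given(
    text=st.text(alphabet=SUPPORTED_CHARS + string.ascii_uppercase, max_size=40),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_roundtrip_over_random_keyboards(text, seed):
    """decode(encode(t)) == t for any supported text and shuffled keyboard."""
    ikey = randomize_ikey(build_reference_ikey(), seed)
    assert decode_message(encode_message(text, ikey), ikey) == text


# ---------------------------------------------------------------------------
# Homopolymer bounds
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "dna, run",
    [("GTTTTC", 4), ("AGCAGCCTGCTGAGCAGC", 2), ("", 0), ("AAAA", 4), ("ACGT", 1)],
)
def test_max_homopolymer_run(dna, run):
    assert max_homopolymer_run(dna) == run


def test_max_homopolymer_run_rejects_non_dna():
    with pytest.raises(InvalidSequenceError):
        max_homopolymer_run("ACGU")


def test_text_homopolymer_bound_exhaustive():
    """No ordered pair of non-function codons exceeds a run of 4."""
    non_function = [c for c in ALL_CODONS if len(set(c)) > 1]
    assert len(non_function) == 60
    worst = max(max_homopolymer_run(a + b) for a in non_function for b in non_function)
    assert worst == 4


def test_digit_homopolymer_bound_exhaustive(reference_ikey):
    """No digit-string encoding exceeds a run of 2 (digit codons are CAT1)."""
    digit_codons = [reference_ikey.codon_of(d) for d in string.digits]
    worst = max(max_homopolymer_run(a + b) for a in digit_codons for b in digit_codons)
    assert worst == 2


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def test_serialize_parse_roundtrip(reference_ikey):
    labels = [b.label for b in reference_ikey.buttons]
    assert parse_ikey_record(serialize_ikey(reference_ikey), labels) == reference_ikey
    shuffled = randomize_ikey(reference_ikey, 42)
    assert parse_ikey_record(serialize_ikey(shuffled), labels) == shuffled


def test_parse_record_validates_shape(reference_ikey):
    labels = [b.label for b in reference_ikey.buttons]
    record = serialize_ikey(reference_ikey).sequence
    with pytest.raises(MalformedRecordError):
        parse_ikey_record(record[:-1], labels)  # 211 nt
    with pytest.raises(MalformedRecordError):
        # an 11th flank T displaced into the interior shortens a flank
        parse_ikey_record(record[1:] + "A", labels)
    with pytest.raises(MalformedRecordError):
        parse_ikey_record(record, labels[:10])


def test_parse_record_rejects_duplicate_codons(reference_ikey):
    labels = [b.label for b in reference_ikey.buttons]
    interior = PBZ38_INTERIOR[:3] * 64
    with pytest.raises(ValidationError):
        parse_ikey_record("T" * 10 + interior + "T" * 10, labels)


def test_ikey_invariants_enforced(reference_ikey):
    with pytest.raises(ValidationError):
        IKey(reference_ikey.buttons[:63])
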