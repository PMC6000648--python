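"""Codon-anticodon decoding model.

The genetic code, Watson-Crick codon/anticodon correspondence, and the
wobble/modification pairing rules that determine which mRNA codons a tRNA
anticodon can read.  Anticodons are 3-letter RNA strings read 5'->3'
(structural positions 34, 35, 36); position 34 is the wobble base that pairs
with the third position of the codon.

Anticodon families group anticodons by their wobble base: an "ANN" anticodon
has A at position 34 and Watson-Crick-decodes an NNU codon, "CNN" decodes
NNG, "GNN" decodes NNC, and "UNN" decodes NNA.

Archaeal genomes typically carry only 44 of the 61 possible sense
anticodon types: all 16 ANN anticodons plus UAU are missing, and their codons
are read instead through G34 wobble (NNU/NNC), cm5U-modified U34 (NNA/NNG)
and agmatidine-modified CAU (AUA).  ``repertoire_coverage`` makes that
argument checkable for any repertoire and rule set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml
from Bio.Data import CodonTable

RNA_BASES = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

#: amino-acid one->three letter codes used for matrix column labels
AA_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


class DecodingError(ValueError):
    """Invalid codon/anticodon input or rule-set configuration."""


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U; validate the alphabet."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - set(RNA_BASES)
    if bad:
        raise DecodingError(f"non-RNA characters {sorted(bad)!r} in {seq!r}")
    return s


def reverse_complement(seq: str) -> str:
    s = normalize_rna(seq)
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def watson_crick_anticodon(codon: str) -> str:
    """The anticodon that pairs a codon by strict Watson-Crick rules.

    Both strands are read 5'->3', so the anticodon is the reverse
    complement of the codon (AUG -> CAU); the function is an involution.
    """
    codon = normalize_rna(codon)
    if len(codon) != 3:
        raise DecodingError(f"codon must have length 3, got {codon!r}")
    return reverse_complement(codon)


#: the Watson-Crick codon of an anticodon -- same involution.
watson_crick_codon = watson_crick_anticodon


def anticodon_family(anticodon: str) -> str:
    """Family label (ANN/CNN/GNN/UNN) from the wobble base at position 34."""
    ac = normalize_rna(anticodon)
    if len(ac) != 3:
        raise DecodingError(f"anticodon must have length 3, got {anticodon!r}")
    return ac[0] + "NN"


class GeneticCode:
    """A 64-codon translation table over the RNA alphabet.

    Parameters
    ----------
    table:
        Mapping from every one of the 64 codons to a one-letter amino-acid
        code or ``"*"`` for stop.
    """

    STOP = "*"

    def __init__(self, table: Mapping[str, str]):
        tab = {normalize_rna(c): aa for c, aa in table.items()}
        if len(tab) != 64:
            raise DecodingError(f"genetic code must cover 64 codons, got {len(tab)}")
        self.table: dict[str, str] = tab
        self._stops = frozenset(c for c, aa in tab.items() if aa == self.STOP)
        self._sense = frozenset(c for c in tab if c not in self._stops)

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard genetic code (UAA/UAG/UGA stops, 61 sense codons)."""
        bio = CodonTable.standard_rna_table
        table = dict(bio.forward_table)
        for stop in bio.stop_codons:
            table[stop] = cls.STOP
        return cls(table)

    @property
    def stop_codons(self) -> frozenset[str]:
        return self._stops

    @property
    def sense_codons(self) -> frozenset[str]:
        return self._sense

    def amino_acid(self, codon: str) -> str:
        return self.table[normalize_rna(codon)]

    def synonymous_family(self, amino_acid: str) -> frozenset[str]:
        """All sense codons translated to ``amino_acid``."""
        return frozenset(c for c in self._sense if self.table[c] == amino_acid)

    def amino_acids(self) -> frozenset[str]:
        return frozenset(aa for aa in self.table.values() if aa != self.STOP)

    def is_sense_anticodon(self, anticodon: str) -> bool:
        """True if the anticodon's Watson-Crick codon is a sense codon."""
        return watson_crick_codon(anticodon) in self._sense


def sense_codons(code: GeneticCode) -> frozenset[str]:
    """All codons of ``code`` that are not stops (61 for the standard code)."""
    return code.sense_codons


def sense_anticodons(code: GeneticCode | None = None) -> frozenset[str]:
    """Watson-Crick anticodons of all sense codons (61 distinct types)."""
    code = code or GeneticCode.standard()
    return frozenset(watson_crick_anticodon(c) for c in code.sense_codons)


def core_repertoire(code: GeneticCode | None = None) -> frozenset[str]:
    """The 44-type anticodon repertoire typical of archaeal genomes.

    All sense anticodons except the 16 A-starting (ANN) types and UAU, the
    17 types that are essentially never observed in Archaea.
    """
    return frozenset(
        a for a in sense_anticodons(code) if a[0] != "A" and a != "UAU"
    )


@dataclass(frozen=True)
class WobbleRule:
    """Pairing ability of a wobble base, optionally modification-gated.

    ``pairs_third`` is the set of codon third-position bases the wobble base
    can pair when ``modification`` (None = unmodified) is in effect.
    """

    wobble_base: str
    modification: str | None
    pairs_third: frozenset[str]


@dataclass(frozen=True)
class SpecialRule:
    """Whole-codon retargeting keyed by a specific anticodon + modification.

    When ``exclusive`` the target codons *replace* the anticodon's wobble
    repertoire (e.g. a modification that abolishes the original pairing);
    otherwise they are added to it.
    """

    anticodon: str
    modification: str
    target_codons: frozenset[str]
    exclusive: bool = False


@dataclass
class ModificationRuleSet:
    """The wobble/modification rules that extend anticodon decoding."""

    wobble_rules: list[WobbleRule] = field(default_factory=list)
    special_rules: list[SpecialRule] = field(default_factory=list)

    @classmethod
    def default(cls) -> "ModificationRuleSet":
        """The rule set used for the archaeal decoding arguments.

        G34 wobbles onto C and U; unmodified U34 pairs only A; cm5U
        (5-carboxymethyluridine, installed by Elp3) lets U34 pair G as well;
        C34 and A34 pair only their Watson-Crick partners; agmatidine on the
        CAU anticodon additionally targets the isoleucine codon AUA.  Other
        wobble modifications (queuosine, cmnm5U, cmo5U, inosine, lysidine,
        pseudouridine) are representable in the same format but not shipped.
        """
        return cls(
            wobble_rules=[
                WobbleRule("G", None, frozenset({"C", "U"})),
                WobbleRule("U", None, frozenset({"A"})),
                WobbleRule("U", "cm5U", frozenset({"A", "G"})),
                WobbleRule("C", None, frozenset({"G"})),
                WobbleRule("A", None, frozenset({"U"})),
            ],
            special_rules=[
                SpecialRule("CAU", "agmatidine", frozenset({"AUA"})),
            ],
        )

    @property
    def modification_names(self) -> frozenset[str]:
        names = {r.modification for r in self.wobble_rules if r.modification}
        names |= {r.modification for r in self.special_rules}
        return frozenset(names)

    # -- serialization -------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "wobble_rules": [
                {
                    "wobble_base": r.wobble_base,
                    "modification": r.modification,
                    "pairable_third_bases": sorted(r.pairs_third),
                }
                for r in self.wobble_rules
            ],
            "special_rules": [
                {
                    "anticodon": r.anticodon,
                    "modification": r.modification,
                    "target_codons": sorted(r.target_codons),
                    "exclusive": r.exclusive,
                }
                for r in self.special_rules
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModificationRuleSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        wobble = [
            WobbleRule(
                normalize_rna(r["wobble_base"]),
                r.get("modification"),
                frozenset(normalize_rna(b) for b in r["pairable_third_bases"]),
            )
            for r in doc.get("wobble_rules", [])
        ]
        special = [
            SpecialRule(
                normalize_rna(r["anticodon"]),
                r["modification"],
                frozenset(normalize_rna(c) for c in r["target_codons"]),
                bool(r.get("exclusive", False)),
            )
            for r in doc.get("special_rules", [])
        ]
        return cls(wobble, special)


def wobble_decoded_codons(
    anticodon: str,
    ruleset: ModificationRuleSet | None = None,
    enabled_mods: Iterable[str] = (),
    code: GeneticCode | None = None,
) -> frozenset[str]:
    """Sense codons an anticodon can decode under the enabled modifications.

    The Watson-Crick codon is always included (unless a special rule
    declares exclusive retargeting); stop codons are never included.
    """
    ac = normalize_rna(anticodon)
    if len(ac) != 3:
        raise DecodingError(f"anticodon must have length 3, got {anticodon!r}")
    ruleset = ruleset if ruleset is not None else ModificationRuleSet.default()
    code = code or GeneticCode.standard()
    mods = frozenset(enabled_mods)
    unknown = mods - ruleset.modification_names
    if unknown:
        raise DecodingError(f"unknown modification(s): {sorted(unknown)}")

    # codon positions 1-2 pair anticodon positions 36-35 by Watson-Crick
    prefix = _COMPLEMENT[ac[2]] + _COMPLEMENT[ac[1]]
    third = {_COMPLEMENT[ac[0]]}  # WC partner of the wobble base
    for rule in ruleset.wobble_rules:
        if rule.wobble_base == ac[0] and (
            rule.modification is None or rule.modification in mods
        ):
            third |= rule.pairs_third
    codons = {prefix + b for b in third}

    exclusive_targets: set[str] | None = None
    for rule in ruleset.special_rules:
        if rule.anticodon == ac and rule.modification in mods:
            if rule.exclusive:
                exclusive_targets = (exclusive_targets or set()) | set(rule.target_codons)
            else:
                codons |= rule.target_codons
    if exclusive_targets is not None:
        codons = exclusive_targets
    return frozenset(codons) & code.sense_codons


def repertoire_coverage(
    anticodons: Iterable[str],
    ruleset: ModificationRuleSet | None = None,
    enabled_mods: Iterable[str] = (),
    code: GeneticCode | None = None,
) -> tuple[frozenset[str], frozenset[str]]:
    """Partition the sense codons into (covered, orphans) for a repertoire.

    ``covered`` is the union of :func:`wobble_decoded_codons` over the
    repertoire; ``orphans`` are the sense codons no anticodon reaches.
    Suppressor anticodons (whose Watson-Crick codon is a stop) are dropped
    with a warning.
    """
    code = code or GeneticCode.standard()
    ruleset = ruleset if ruleset is not None else ModificationRuleSet.default()
    covered: set[str] = set()
    for ac in anticodons:
        ac = normalize_rna(ac)
        if not code.is_sense_anticodon(ac):
            warnings.warn(
                f"suppressor anticodon {ac} (Watson-Crick codon is a stop) "
                "ignored in coverage",
                stacklevel=2,
            )
            continue
        covered |= wobble_decoded_codons(ac, ruleset, enabled_mods, code)
    orphans = code.sense_codons - covered
    return frozenset(covered), frozenset(orphans)


def family_members(family: str, code: GeneticCode | None = None) -> frozenset[str]:
    """Sense anticodons belonging to a wobble family (e.g. ``"CNN"``).

    Note: for CNN this returns 15 types (one per sense NNG codon); surveys
    that split CAU into initiator and elongator Met count 16 CNN tRNAs.
    """
    if len(family) != 3 or family[1:] != "NN" or family[0] not in RNA_BASES:
        raise DecodingError(f"bad family label {family!r}")
    return frozenset(a for a in sense_anticodons(code) if a[0] == family[0])
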