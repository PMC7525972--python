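"""Bundled example focal-interaction networks (mouse gut genera).

Six curated signed star networks around focal genera from two mouse
cohorts — a sham-surgery control group ("sham") and a spared-nerve-injury
group ("sni") — shipped as worked examples and regression fixtures for
:func:`glvnet.topology.focal_report`.  Each fixture records the genera
that influence the focal genus (by sign) and the genera the focal genus
influences (by sign); every fixture is an independent star graph because
the published per-focal lists are not mutually consistent enough to merge
into one graph without changing the per-focal counts.
"""

from __future__ import annotations

import pandas as pd

from glvnet.inference import ConsensusNetwork

# {(group, focal): {direction_sign: [genus, ...]}}
FOCAL_TABLES: dict[tuple[str, str], dict[str, list[str]]] = {
    ("sham", "Oscillospira"): {
        "influenced_by_positive": [
            "Barnesiella",
            "Erysipelotrichaceae_unclassified",
            "Lactobacillus",
            "Mollicutes_RF9",
            "Mollicutes_unclassified",
            "Streptococcus",
        ],
        "influenced_by_negative": [
            "Clostridiales_unclassified",
            "Firmicutes_unclassified",
            "Peptococcaceae",
            "Ruminococcus",
            "Ruminococcaceae_unclassified",
        ],
        "influences_positive": [
            "Acetanaerobacterium",
            "Bacteroidales_unclassified",
            "Clostridium_Candidatus_Arthromitus",
            "Lachnospiraceae_unclassified",
            "Porphyromonadaceae_unclassified",
            "Ruminococcaceae_Incertae_Sedis",
        ],
        "influences_negative": [
            "Actinobacteria_unclassified",
            "Akkermansia",
            "Allobaculum",
            "Bacteroidales_S24-7",
            "Bifidobacterium",
            "Clostridium_unclassified",
            "Olsenella",
            "Parabacteroides",
            "Parasutterella",
            "Peptococcaceae_unclassified",
            "Ruminococcaceae_uncultured",
            "Ruminococcus",
            "Turicibacter",
        ],
    },
    ("sni", "Staphylococcus"): {
        "influenced_by_positive": [
            "Bacteroides",
            "Clostridium_unclassified",
            "Erysipelotrichaceae_Incertae_Sedis",
            "Lachnospira",
            "Parabacteroides",
            "Ruminococcus",
            "Turicibacter",
        ],
        "influenced_by_negative": [
            "Bacteroidales_unclassified",
            "Candidate_division_TM7",
            "Eubacterium",
            "Lachnospiraceae_unclassified",
            "Mollicutes_unclassified",
            "Roseburia",
            "Ruminococcaceae_Incertae_Sedis",
        ],
        "influences_positive": [
            "Bacteria_unclassified",
            "Clostridiales_unclassified",
            "Desulfovibrio",
            "Firmicutes_unclassified",
            "Hydrogenoanaerobacterium",
            "Lachnospiraceae_Incertae_Sedis",
            "Lachnospiraceae_unclassified",
            "Lachnospiraceae_uncultured",
            "Mucispirillum",
            "Oscillibacter",
            "Oscillospira",
            "Ruminococcaceae_Incertae_Sedis",
            "Ruminococcaceae_unclassified",
        ],
        "influences_negative": [
            "Akkermansia",
            "Bacteroidales_S24-7",
            "Lactobacillus",
        ],
    },
    ("sham", "Lactobacillus"): {
        "influenced_by_positive": [
            "Clostridium_unclassified",
            "Eubacterium",
            "Firmicutes_unclassified",
            "Parabacteroides",
            "Parasutterella",
            "Ruminococcus",
        ],
        "influenced_by_negative": [
            "Clostridia_unclassified",
        ],
        "influences_positive": [
            "Desulfovibrio",
            "Lachnospiraceae_uncultured",
            "Oscillibacter",
            "Ruminococcaceae_Incertae_Sedis",
            "Ruminococcaceae_unclassified",
        ],
        "influences_negative": [
            "Adlercreutzia",
            "Bifidobacterium",
            "Coprobacillus",
            "Porphyromonadaceae_unclassified",
            "Ruminococcus",
            "Turicibacter",
        ],
    },
    ("sham", "Bifidobacterium"): {
        "influenced_by_positive": [
            "Adlercreutzia",
            "Turicibacter",
        ],
        "influenced_by_negative": [
            "Lactobacillus",
            "Bacteroidales_S24-7",
            "Erysipelotrichaceae_unclassified",
            "Barnesiella",
            "Enterococcus",
            "Mollicutes_unclassified",
            "Oscillospira",
        ],
        "influences_positive": [
            "Acinetobacter",
            "Ruminococcus",
        ],
        "influences_negative": [
            "Coriobacteriaceae_unclassified",
        ],
    },
    ("sni", "Lactobacillus"): {
        "influenced_by_positive": [
            "Hydrogenoanaerobacterium",
            "Parasutterella",
            "Staphylococcus",
        ],
        "influenced_by_negative": [
            "Bacteroidales_unclassified",
            "Barnesiella",
            "Lachnospiraceae_unclassified",
        ],
        "influences_positive": [
            "Bacteria_unclassified",
            "Clostridiales_unclassified",
            "Desulfovibrio",
            "Lachnospiraceae_uncultured",
            "Parabacteroides",
        ],
        "influences_negative": [],
    },
    ("sni", "Bifidobacterium"): {
        "influenced_by_positive": [
            "Acetanaerobacterium",
        ],
        "influenced_by_negative": [
            "Akkermansia",
            "Clostridium_Candidatus_Arthromitus",
            "Lachnospiraceae_uncultured",
            "Ruminococcus",
            "Turicibacter",
        ],
        "influences_positive": [
            "Acetanaerobacterium",
            "Barnesiella",
            "Candidate_division_TM7",
            "Erysipelotrichaceae_unclassified",
            "Eubacterium",
            "Mollicutes_RF9",
            "Ruminococcaceae_uncultured",
        ],
        "influences_negative": [
            "Allobaculum",
        ],
    },
}


def available_examples() -> list[tuple[str, str]]:
    """(group, focal) keys of the bundled focal networks."""
    return sorted(FOCAL_TABLES)


def example_focal_network(group: str, focal: str) -> ConsensusNetwork:
    """Build the star :class:`ConsensusNetwork` around one bundled focal genus.

    Edge strengths are placeholder unit magnitudes with the recorded sign;
    support is 1.0 (the fixtures carry signs and directions only).
    """
    key = (group, focal)
    if key not in FOCAL_TABLES:
        raise KeyError(
            f"no bundled network for {key}; available: {available_examples()}"
        )
    lists = FOCAL_TABLES[key]
    records = []
    for name, sign, incoming in (
        ("influenced_by_positive", 1, True),
        ("influenced_by_negative", -1, True),
        ("influences_positive", 1, False),
        ("influences_negative", -1, False),
    ):
        for genus in lists[name]:
            src, dst = (genus, focal) if incoming else (focal, genus)
            records.append(
                {
                    "source": src,
                    "target": dst,
                    "sign": sign,
                    "support": 1.0,
                    "mean_strength": float(sign),
                }
            )
    edges = pd.DataFrame(records, columns=list(ConsensusNetwork.EDGE_COLUMNS))
    taxa = sorted({focal, *edges["source"], *edges["target"]})
    return ConsensusNetwork(taxa=taxa, edges=edges, cutoff=0.7, n_members=1)
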