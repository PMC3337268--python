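"""Builders for the packaged toxicology vocabulary ontologies.

Two vocabularies are built programmatically and shipped as OWL/Turtle files:

* the **toxicological endpoint** ontology — study types (carcinogenicity,
  mutagenicity variants, repeated-dose, aquatic toxicity), test systems and
  test results, used to annotate what a dataset feature measures;
* the **organs and effects** ontology — the 13 rodent organ systems with a
  skeleton of anatomical structures, cell types, hormones/enzymes, and the
  effect → pathological effect → diagnostic feature chain used for in-vivo
  study findings.

Both are vocabulary scaffolds with demo anatomical/effect content for the
respiratory and digestive tracts, not full nomenclature reproductions.
Builds are deterministic, so the emitted files are byte-stable.
"""

from __future__ import annotations

from .owl_model import OntologyModel

ENDPOINT_BASE_IRI = "http://example.org/toxlift/endpoint"
ORGANS_BASE_IRI = "http://example.org/toxlift/organs-effects"

#: the five top-level toxicity study types
STUDY_TYPES = (
    "Carcinogenicity",
    "InVitroBacterialMutagenicity",
    "InVivoMicronucleusMutagenicity",
    "RepeatedDoseToxicity",
    "AquaticToxicity",
)

#: the 13 organ systems, label -> full human-readable phrase
ORGAN_SYSTEMS = {
    "DigestiveSystem": "digestive system",
    "RespiratorySystem": "respiratory system",
    "CirculatorySystem": "circulatory system",
    "EndocrineSystem": "endocrine system",
    "MaleGenitalSystem": "male genital system",
    "FemaleGenitalSystem": "female genital system",
    "HematopoieticSystem": "hematopoietic system",
    "IntegumentarySystem": "integumentary system",
    "BodyCavities": "body cavities",
    "NervousSystemAndSpecialSenseOrgans": "nervous system and special sense organs",
    "UrinarySystem": "urinary system",
    "MusculoskeletalSystem": "musculoskeletal system",
    "ImmuneSystemAndLymphaticOrgans": "immune system and lymphatic organs",
}


def build_endpoint_ontology() -> OntologyModel:
    """Toxicological endpoint vocabulary: study types, test systems, results."""
    m = OntologyModel(base_iri=ENDPOINT_BASE_IRI)
    m.add_class("ToxicityStudyType", "Category of toxicity study an endpoint belongs to.")
    for label in STUDY_TYPES:
        m.add_class(label)
        m.add_subclass(label, "ToxicityStudyType")

    for label in ("Chronic", "SubChronic", "SubAcute"):
        m.add_class(label)
        m.add_subclass(label, "RepeatedDoseToxicity")

    m.add_class("TestSystem", "The biological system and exposure design of a study.")
    for label in ("Strain", "Species", "Sex", "RouteOfExposure"):
        m.add_class(label)
        m.add_subclass(label, "TestSystem")

    m.add_class("TestResult", "The recorded outcome of a toxicity study.")
    for label in ("ToxicityMeasure", "TestCall", "ModeOfAction", "TargetSite"):
        m.add_class(label)
        m.add_subclass(label, "TestResult")

    m.add_object_property("hasTestSystem", ("ToxicityStudyType",), ("TestSystem",))
    m.add_object_property("hasTestResult", ("ToxicityStudyType",), ("TestResult",))
    return m


# demo anatomical content: organ system -> structures -> (synonym, cells, enzymes)
_DEMO_STRUCTURES = {
    "RespiratorySystem": {
        "NasalCavity": (("nose cavity",), ("GobletCell",), ()),
        "Trachea": (("windpipe",), ("CiliatedCell",), ()),
        "Lung": (("pulmo",), ("ClaraCell", "AlveolarMacrophage"), ("SurfactantProteinB",)),
    },
    "DigestiveSystem": {
        "Esophagus": (("gullet",), (), ()),
        "Stomach": (("ventriculus",), ("ParietalCell",), ("Pepsin",)),
        "SmallIntestine": (("small bowel",), ("Enterocyte",), ("Lactase",)),
    },
}

# demo effects chain for the respiratory tract
_DEMO_EFFECTS = {
    "Inflammation": {
        "Bronchiolitis": ("PeribronchiolarInfiltrate", "LuminalExudate"),
    },
    "Degeneration": {
        "OlfactoryEpithelialNecrosis": ("CellularDebris", "EpithelialVacuolation"),
    },
}


def build_organs_effects_ontology() -> OntologyModel:
    """Organ-system anatomy skeleton plus the effects/diagnostic-feature chain.

    Organ systems focus on rodents, the common test species in repeated-dose
    and carcinogenicity studies; species specificity is future work and is
    only marked by an annotation here.
    """
    m = OntologyModel(base_iri=ORGANS_BASE_IRI)
    m.add_class("OrganSystem",
                "Top-level organ system; content focuses on rodent anatomy.")
    for label, phrase in ORGAN_SYSTEMS.items():
        m.add_class(label, phrase)
        m.add_subclass(label, "OrganSystem")

    m.add_class("AnatomicalStructure",
                "Organ or tissue component of an organ system, down to "
                "histological parts.")
    m.add_class("CellType", "Main cell type found in an organ tissue.")
    m.add_class("HormoneOrEnzyme", "Main hormone or enzyme produced in an organ.")
    m.add_object_property("hasAnatomicalStructure", ("OrganSystem",),
                          ("AnatomicalStructure",))
    m.add_object_property("hasCellType", ("AnatomicalStructure",), ("CellType",))
    m.add_object_property("hasHormoneOrEnzyme", ("AnatomicalStructure",),
                          ("HormoneOrEnzyme",))
    m.add_datatype_property("hasSynonym", ("AnatomicalStructure",), "string")

    # demo structures are subclasses; the has* properties stay generic so
    # their domains/ranges remain the scaffold classes, not ad-hoc unions
    for system, structures in _DEMO_STRUCTURES.items():
        for structure, (synonyms, cells, enzymes) in structures.items():
            comment = ("Synonyms: " + ", ".join(synonyms)) if synonyms else None
            m.add_class(structure, f"Part of {system}." +
                        (f" {comment}" if comment else ""))
            m.add_subclass(structure, "AnatomicalStructure")
            for cell in cells:
                m.add_class(cell)
                m.add_subclass(cell, "CellType")
            for enzyme in enzymes:
                m.add_class(enzyme)
                m.add_subclass(enzyme, "HormoneOrEnzyme")

    # effects side: effect -> pathological effect -> diagnostic feature
    m.add_class("Effect", "Observed neoplastic or non-neoplastic effect class.")
    m.add_class("PathologicalEffect", "Localized pathological manifestation.")
    m.add_class("DiagnosticFeature", "Detailed histological diagnostic criterion.")
    m.add_object_property("hasPathologicalEffect", ("Effect",), ("PathologicalEffect",))
    m.add_object_property("hasDiagnosticFeature", ("PathologicalEffect",),
                          ("DiagnosticFeature",))
    m.add_object_property("hasTargetStructure", ("PathologicalEffect",),
                          ("AnatomicalStructure",))
    for effect, path_effects in _DEMO_EFFECTS.items():
        m.add_class(effect)
        m.add_subclass(effect, "Effect")
        for path_effect, features in path_effects.items():
            m.add_class(path_effect)
            m.add_subclass(path_effect, "PathologicalEffect")
            for feature in features:
                m.add_class(feature)
                m.add_subclass(feature, "DiagnosticFeature")
    return m
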