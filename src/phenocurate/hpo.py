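"""A small bundled subset of HPO term ids and labels.

Enough of the Human Phenotype Ontology to exercise curation workflows and
term-existence checks without downloading the ontology.  The subset leans on
connective-tissue and skeletal phenotypes (the Marfan-syndrome worked example)
plus a spread of common rare-disease annotations.  Synthetic corpora instead
use reserved fake ranges (``HP:9xxxxxx``) that never collide with these.
"""

from __future__ import annotations

HPO_SUBSET: dict[str, str] = {
    "HP:0000098": "Tall stature",
    "HP:0000268": "Dolichocephaly",
    "HP:0000365": "Hearing impairment",
    "HP:0000486": "Strabismus",
    "HP:0000501": "Glaucoma",
    "HP:0000545": "Myopia",
    "HP:0000767": "Pectus excavatum",
    "HP:0000768": "Pectus carinatum",
    "HP:0001083": "Ectopia lentis",
    "HP:0001166": "Arachnodactyly",
    "HP:0001250": "Seizure",
    "HP:0001252": "Hypotonia",
    "HP:0001263": "Global developmental delay",
    "HP:0001382": "Joint hypermobility",
    "HP:0001519": "Disproportionate tall stature",
    "HP:0001634": "Mitral valve prolapse",
    "HP:0001653": "Mitral regurgitation",
    "HP:0001659": "Aortic regurgitation",
    "HP:0001763": "Pes planus",
    "HP:0002097": "Emphysema",
    "HP:0002107": "Pneumothorax",
    "HP:0002108": "Spontaneous pneumothorax",
    "HP:0002616": "Aortic root aneurysm",
    "HP:0002650": "Scoliosis",
    "HP:0002705": "High, narrow palate",
    "HP:0002751": "Kyphoscoliosis",
    "HP:0002827": "Hip dislocation",
    "HP:0003179": "Protrusio acetabuli",
    "HP:0003302": "Spondylolisthesis",
    "HP:0004927": "Pulmonary artery dilatation",
    "HP:0004933": "Ascending aortic dissection",
    "HP:0004970": "Ascending tubular aorta aneurysm",
    "HP:0005059": "Arthrogryposis-like hand anomaly",
    "HP:0007800": "Increased axial length of the globe",
    "HP:0012019": "Lens luxation",
    "HP:0012385": "Camptodactyly",
    "HP:0012432": "Chronic fatigue",
    "HP:0012773": "Reduced upper to lower segment ratio",
    "HP:0100775": "Dural ectasia",
    "HP:0012499": "Striae distensae",
}


def label_of(term_id: str) -> str | None:
    """Label for a term id, or None when outside the bundled subset."""
    return HPO_SUBSET.get(term_id)


def is_known(term_id: str) -> bool:
    return term_id in HPO_SUBSET
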