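"""Synthetic fixture vocabulary, gold standards, error injection and
trial simulation.

The fixture thesaurus covers every descriptor and subheading named in the
twelve gold-standard study questions, in English and French, with enough
hierarchy to exercise every over-/under-specification path (e.g.
dysgeusia below taste disorders; overweight and obesity as siblings below
a body-weight parent).  Tree numbers are synthetic (MeSH-flavoured but
invented); only the relations the accepted query variants rely on are
meaningful.  French labels beyond those fixed by the study material are
likewise invented for the fixture.

On top of it, :func:`perturb` inverts each error-taxonomy definition to
inject exactly one classifiable error into a gold query, and
:func:`simulate_trial` samples whole two-arm trials for end-to-end tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

from .grading import ErrorKind, ErrorReport, GoldStandard, Submission, extract_terms, grade
from .query import BoolNode, QueryNode, TermNode, parse, serialize
from .thesaurus import (
    Descriptor,
    Qualifier,
    RecordKind,
    Thesaurus,
    write_mesh_xml,
    write_translations,
)

# ---------------------------------------------------------------------------
# vocabulary tables
# ---------------------------------------------------------------------------

#: qualifier rows: (ui, en label, fr label, tree numbers, en synonyms, fr synonyms)
_QUALIFIERS = [
    ("Q000008", "administration and dosage", "administration et posologie", ["Y02"],
     ["administration & dosage", "dosage"], ["posologie"]),
    ("Q000009", "adverse effects", "effets indésirables", ["Y01"],
     ["adverse effect", "side effects"], ["effets secondaires"]),
    ("Q000032", "analysis", "analyse", ["Y04"], [], []),
    ("Q000097", "blood", "sang", ["Y04.150"], [], []),
    ("Q000139", "chemically induced", "induit chimiquement", ["Y05.200"], [], []),
    ("Q000175", "diagnosis", "diagnostic", ["Y07"], [], []),
    ("Q000000981", "diagnostic imaging", "imagerie diagnostique", ["Y07.400"], [], []),
    ("Q000178", "diet therapy", "diétothérapie", ["Y11.200"], [], []),
    ("Q000187", "drug effects", "effets des médicaments", ["Y10"], [], []),
    ("Q000188", "drug therapy", "traitement médicamenteux", ["Y11.300"], [], []),
    ("Q000453", "epidemiology", "épidémiologie", ["Y06"], [], []),
    ("Q000209", "etiology", "étiologie", ["Y05"], [], []),
    ("Q000506", "poisoning", "intoxication", ["Y01.600"], [], []),
    ("Q000517", "prevention and control", "prévention et contrôle", ["Y13"],
     ["prevention & control"], [], ),
    ("Q000628", "therapy", "thérapeutique", ["Y11"], [], []),
    ("Q000652", "urine", "urine", ["Y04.800"], [], []),
]

# standard allowed-qualifier bundles
_DISEASE_Q = [
    "Q000097", "Q000139", "Q000175", "Q000188", "Q000209",
    "Q000453", "Q000517", "Q000628",
]
_CHEM_Q = ["Q000008", "Q000009", "Q000032", "Q000097", "Q000506"]

#: descriptor rows:
#: (ui, en, fr, trees, allowed qualifiers, en synonyms, fr synonyms, kind)
_DESCRIPTORS = [
    # neoplasms branch
    ("D009369", "Neoplasms", "tumeurs", ["C04"], _DISEASE_Q,
     ["cancer", "tumors"], ["cancers"], "descriptor"),
    ("D001943", "Breast Neoplasms", "tumeurs du sein", ["C04.588.180"], _DISEASE_Q,
     ["breast cancer", "breast tumors"], ["cancer du sein"], "descriptor"),
    ("D900101", "Unilateral Breast Neoplasms", "tumeurs unilatérales du sein",
     ["C04.588.180.500"], _DISEASE_Q, [], [], "descriptor"),
    ("D002583", "Uterine Cervical Neoplasms", "tumeurs du col de l'utérus",
     ["C04.588.945"], _DISEASE_Q, ["cervical cancer"], ["cancer du col de l'utérus"],
     "descriptor"),
    ("D007889", "Leiomyoma", "léiomyome", ["C04.557.450"], _DISEASE_Q,
     ["fibroid tumor", "fibroid"], ["fibrome"], "descriptor"),
    ("D900102", "Leiomyoma, Epithelioid", "léiomyome épithélioïde",
     ["C04.557.450.390"], _DISEASE_Q, [], [], "descriptor"),
    # injuries
    ("D012421", "Rupture", "rupture", ["C26.760"], _DISEASE_Q, [], [], "descriptor"),
    ("D012422", "Rupture, Spontaneous", "rupture spontanée", ["C26.760.657"],
     _DISEASE_Q, ["spontaneous rupture"], [], "descriptor"),
    # skin and hair
    ("D012871", "Skin Diseases", "maladies de la peau", ["C17.800"], _DISEASE_Q,
     ["dermatoses"], ["dermatoses"], "descriptor"),
    ("D006201", "Hair Diseases", "maladies des cheveux", ["C17.800.329"],
     _DISEASE_Q, [], [], "descriptor"),
    ("D000504", "Alopecia", "alopécie", ["C17.800.329.937.122"], _DISEASE_Q,
     ["baldness"], ["calvitie"], "descriptor"),
    ("D000505", "Alopecia Areata", "pelade", ["C17.800.329.937.122.147"],
     _DISEASE_Q, ["alopecia circumscripta"], ["alopécie en aires"], "descriptor"),
    ("D900103", "Alopecia Totalis", "pelade décalvante totale",
     ["C17.800.329.937.122.147.500"], _DISEASE_Q, [], [], "descriptor"),
    ("D012878", "Skin Manifestations", "manifestations cutanées", ["C23.888.885"],
     ["Q000139", "Q000209"], [], [], "descriptor"),
    # chemicals and drugs
    ("D014815", "Vitamins", "vitamines", ["D11.787"], _CHEM_Q, [], [], "descriptor"),
    ("D014807", "Vitamin D", "vitamine D", ["D11.787.935"], _CHEM_Q,
     ["calciferol"], ["calciférol"], "descriptor"),
    ("D002762", "Cholecalciferol", "cholécalciférol", ["D11.787.935.250"], _CHEM_Q,
     ["vitamin d3"], ["vitamine d3"], "descriptor"),
    ("D012492", "Salts", "sels", ["D01.857"], _CHEM_Q, [], [], "descriptor"),
    ("D012965", "Sodium Chloride", "chlorure de sodium", ["D01.857.828"], _CHEM_Q,
     ["common salt", "table salt"], ["sel de table"], "descriptor"),
    ("D900104", "Saline Solution, Hypertonic", "solution saline hypertonique",
     ["D01.857.828.750"], _CHEM_Q, [], [], "descriptor"),
    ("D004791", "Enzyme Inhibitors", "inhibiteurs enzymatiques", ["D27.505.519"],
     _CHEM_Q, [], [], "descriptor"),
    ("D000493", "Allopurinol", "allopurinol", ["D27.505.519.389"], _CHEM_Q,
     [], [], "descriptor"),
    ("D000890", "Anti-Infective Agents", "anti-infectieux", ["D27.505.954.122"],
     _CHEM_Q, [], [], "descriptor"),
    ("D000900", "Anti-Bacterial Agents", "antibactériens",
     ["D27.505.954.122.085"], _CHEM_Q, ["antibiotics"], ["antibiotiques"],
     "descriptor"),
    ("D900105", "Adrenal Cortex Hormones", "hormones corticosurrénaliennes",
     ["D06.472.040"], _CHEM_Q, ["corticosteroids"], ["corticostéroïdes"],
     "descriptor"),
    ("D005938", "Glucocorticoids", "glucocorticoïdes", ["D06.472.040.585"],
     _CHEM_Q, [], [], "descriptor"),
    # diagnosis and procedures
    ("D003937", "Diagnostic Techniques and Procedures",
     "techniques et procédures diagnostiques", ["E01.370"], [], [], [], "descriptor"),
    ("D008403", "Mass Screening", "dépistage de masse", ["E01.370.500"], [],
     ["screening"], ["dépistage"], "descriptor"),
    ("D900106", "Multiphasic Screening", "dépistage multiple",
     ["E01.370.500.500"], [], [], [], "descriptor"),
    ("D019411", "Clinical Laboratory Techniques", "techniques de laboratoire clinique",
     ["E01.450"], [], [], [], "descriptor"),
    ("D001774", "Blood Chemical Analysis", "analyse chimique du sang",
     ["E01.450.375"], [], ["blood chemistry"], ["chimie du sang"], "descriptor"),
    ("D010147", "Pain Measurement", "mesure de la douleur", ["E01.370.600"], [],
     [], [], "descriptor"),
    ("D059408", "Pain Management", "gestion de la douleur", ["E02.745"], [],
     [], ["prise en charge de la douleur"], "descriptor"),
    ("D007114", "Immunization", "immunisation", ["E02.095"], ["Q000009"],
     [], [], "descriptor"),
    ("D014611", "Vaccination", "vaccination", ["E02.095.895"], ["Q000009"],
     [], [], "descriptor"),
    ("D900107", "Mass Vaccination", "vaccination de masse", ["E02.095.895.500"],
     ["Q000009"], [], [], "descriptor"),
    ("D900108", "Drug Dosage Calculations", "calculs posologiques",
     ["E02.319.306"], [], [], [], "descriptor"),
    # decoy for irrelevant-term injection: unrelated to everything above
    ("D009147", "Music Therapy", "musicothérapie", ["E02.190.525"], [],
     [], [], "descriptor"),
    # diseases, signs and symptoms
    ("D009135", "Muscular Diseases", "maladies musculaires", ["C05.651"],
     _DISEASE_Q, [], [], "descriptor"),
    ("D055948", "Sarcopenia", "sarcopénie", ["C05.651.807"], _DISEASE_Q,
     [], [], "descriptor"),
    ("D001982", "Bronchial Diseases", "maladies des bronches", ["C08.127"],
     _DISEASE_Q, [], [], "descriptor"),
    ("D001249", "Asthma", "asthme", ["C08.127.108"], _DISEASE_Q,
     ["bronchial asthma"], [], "descriptor"),
    ("D900109", "Asthma, Exercise-Induced", "asthme à l'effort",
     ["C08.127.108.110"], _DISEASE_Q, [], [], "descriptor"),
    ("D009461", "Neurologic Manifestations", "manifestations neurologiques",
     ["C23.888.592"], _DISEASE_Q, [], [], "descriptor"),
    ("D010146", "Pain", "douleur", ["C23.888.592.612"], _DISEASE_Q,
     [], ["douleurs"], "descriptor"),
    ("D015746", "Abdominal Pain", "douleur abdominale", ["C23.888.592.612.054"],
     _DISEASE_Q, [], [], "descriptor"),
    ("D013651", "Taste Disorders", "troubles du goût", ["C10.597.751.861"],
     _DISEASE_Q, [], [], "descriptor"),
    ("D004408", "Dysgeusia", "dysgueusie", ["C10.597.751.861.479"], _DISEASE_Q,
     ["taste distortion"], [], "descriptor"),
    ("D900110", "Ageusia", "agueusie", ["C10.597.751.861.119"], _DISEASE_Q,
     [], [], "descriptor"),
    ("D013650", "Taste Perception", "perception du goût", ["F02.830.800"], [],
     ["taste"], ["goût"], "descriptor"),
    ("D006130", "Growth Disorders", "troubles de la croissance", ["C23.550.393"],
     _DISEASE_Q, [], [], "descriptor"),
    # physiology
    ("D900111", "Growth and Development", "croissance et développement",
     ["G07.345"], ["Q000187"], [], [], "descriptor"),
    ("D006128", "Growth", "croissance", ["G07.345.249"], ["Q000187"],
     [], [], "descriptor"),
    ("D001835", "Body Weight", "poids du corps", ["G07.100"], [],
     [], ["poids corporel"], "descriptor"),
    ("D050177", "Overweight", "surpoids", ["G07.100.500"], _DISEASE_Q,
     [], ["surcharge pondérale"], "descriptor"),
    ("D009765", "Obesity", "obésité", ["G07.100.600"], _DISEASE_Q,
     [], [], "descriptor"),
    ("D900112", "Obesity, Morbid", "obésité morbide", ["G07.100.600.500"],
     _DISEASE_Q, [], [], "descriptor"),
    # persons
    ("D009272", "Persons", "personnes", ["M01"], [], [], [], "descriptor"),
    ("D000328", "Adult", "adulte", ["M01.116"], [], [], [], "descriptor"),
    ("D000368", "Aged", "sujet âgé", ["M01.116.100"], [],
     ["elderly"], ["personne âgée"], "descriptor"),
    ("D000369", "Aged, 80 and over", "sujet âgé de 80 ans ou plus",
     ["M01.116.100.080"], [], [], [], "descriptor"),
    ("D007223", "Infant", "nourrisson", ["M01.703"], [], ["infants"], ["bébé"],
     "descriptor"),
    ("D007231", "Infant, Newborn", "nouveau-né", ["M01.703.520"], [],
     ["newborn"], [], "descriptor"),
    # geography
    ("D009656", "North America", "amérique du nord", ["Z01.107.567"],
     ["Q000453"], [], [], "descriptor"),
    ("D014481", "United States", "états-unis", ["Z01.107.567.875"],
     ["Q000453"], ["united states of america", "usa"], ["états-unis d'amérique"],
     "descriptor"),
    # disciplines and information
    ("D004813", "Epidemiology", "épidémiologie", ["H02.403.210"], [],
     [], [], "descriptor"),
    ("D017410", "Practice Guidelines as Topic", "guides de bonne pratique comme sujet",
     ["N05.700.350"], [], ["clinical practice guidelines"],
     ["recommandations"], "descriptor"),
    # publication type (no qualifiers by construction)
    ("D016431", "Practice Guideline", "guide de bonne pratique", ["V02.515"], [],
     ["practice guidelines"], ["recommandation de bonne pratique"],
     "publication_type"),
]


#: the twelve study questions with their accepted gold query variants
GOLD_QUESTIONS: list[GoldStandard] = [
    GoldStandard(
        "Q01", "low",
        {"en": "Fibroid uterus spontaneous rupture",
         "fr": "Rupture spontanée d'un fibrome utérin"},
        ["leiomyoma AND rupture, spontaneous"],
    ),
    GoldStandard(
        "Q02", "low",
        {"en": "Alopecia areata prevention", "fr": "Prévention des pelades"},
        ["alopecia areata/prevention and control"],
    ),
    GoldStandard(
        "Q03", "low",
        {"en": "Vitamin D determination in blood",
         "fr": "Dosage de la vitamine D dans le sang"},
        ["vitamin D/blood",
         "vitamin D/analysis OR vitamin D/blood",
         "vitamin D/blood OR (vitamin D AND blood chemical analysis)"],
    ),
    GoldStandard(
        "Q04", "low",
        {"en": "Sarcopenia for over 65 years old patients",
         "fr": "Sarcopénie chez les patients de plus de 65 ans"},
        ["sarcopenia AND aged"],
    ),
    GoldStandard(
        "Q05", "medium",
        {"en": "Vaccination induced pain in infant",
         "fr": "Douleur au cours de la vaccination des nourrissons"},
        ["infant AND pain AND vaccination",
         "infant AND (pain OR pain measurement OR pain management) AND vaccination"],
    ),
    GoldStandard(
        "Q06", "medium",
        {"en": "Guidelines for breast cancer treatment",
         "fr": "Recommandations sur le traitement du cancer du sein"},
        ["breast neoplasms/therapy AND practice guidelines as topic",
         "breast neoplasms/therapy AND practice guideline"],
    ),
    GoldStandard(
        "Q07", "medium",
        {"en": "Asthma epidemiology in USA",
         "fr": "Epidémiologie de l'asthme aux Etats-Unis"},
        ["asthma/epidemiology AND united states",
         "(asthma/epidemiology OR (asthma AND epidemiology)) AND united states"],
    ),
    GoldStandard(
        "Q08", "medium",
        {"en": "Screening for uterine cervical neoplasm",
         "fr": "Dépistage du cancer du col de l'utérus"},
        ["mass screening AND uterine cervical neoplasms/prevention and control",
         "mass screening AND uterine cervical neoplasms/diagnosis"],
    ),
    GoldStandard(
        "Q09", "high",
        {"en": "Salty taste in the mouth", "fr": "Goût salé dans la bouche"},
        ["sodium chloride AND dysgeusia",
         "sodium chloride AND taste disorders",
         "sodium chloride AND taste perception"],
    ),
    GoldStandard(
        "Q10", "high",
        {"en": "Allopurinol cutaneous side effect",
         "fr": "Effets secondaires cutanés de l'allopurinol"},
        ["allopurinol/adverse effect AND skin diseases/chemically induced",
         "allopurinol/adverse effect AND (skin diseases/chemically induced"
         " OR skin manifestations/chemically induced)"],
    ),
    GoldStandard(
        "Q11", "high",
        {"en": "Glucocorticoids effects on asthmatic patient's growth",
         "fr": "Impact des glucocorticoïdes sur la croissance du patient asthmatique"},
        ["(glucocorticoids/adverse effects) AND (growth/drug effects"
         " OR growth disorders/chemically induced) AND asthma/drug therapy",
         "(glucocorticoids/adverse effects) AND (growth/drug effects"
         " OR growth disorders/etiology) AND asthma/drug therapy"],
    ),
    GoldStandard(
        "Q12", "high",
        {"en": "Antibiotics dosage for overweight or obese patient",
         "fr": "Posologie des antibiotiques chez le patient en surpoids ou obèse"},
        ["anti-bacterial agents/administration and dosage AND (obesity OR overweight)",
         "(anti-bacterial agents/administration and dosage OR"
         " (drug dosage calculations AND anti-bacterial agents))"
         " AND (obesity OR overweight)"],
    ),
]

#: decoy descriptor used for irrelevant-term injection (unrelated to all gold terms)
DECOY_UI = "D009147"

#: query-level error-flag counts from the two-arm evaluation of the query
#: builder (French-interface arm, English-interface arm), used to calibrate
#: the trial simulator.  Arm denominators are inferred from the published
#: counts and percentages (89/235 = 37.9%, 46/257 = 17.9%).
TRIAL_FLAG_COUNTS: dict[str, tuple[int, int]] = {
    "perfect": (89, 46),
    ErrorKind.IRRELEVANT_TERM.value: (52, 83),
    ErrorKind.OVERSPEC_DESCRIPTOR.value: (28, 39),
    ErrorKind.OVERSPEC_QUALIFIER.value: (17, 17),
    ErrorKind.UNDERSPEC_DESCRIPTOR.value: (41, 87),
    ErrorKind.UNDERSPEC_QUALIFIER.value: (48, 72),
    ErrorKind.INCORRECT_OPERATOR.value: (1, 1),
    ErrorKind.SYNTAX_ERROR.value: (2, 4),
}
TRIAL_ARM_TOTALS: tuple[int, int] = (235, 257)
TRIAL_ARMS: tuple[str, str] = ("french", "english")


# ---------------------------------------------------------------------------
# fixture thesaurus
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    languages: tuple[str, ...] = ("en", "fr")
    include_table_vocabulary: bool = True
    extra_random_descriptors: int = 0


def build_fixture_thesaurus(spec: FixtureSpec = FixtureSpec()) -> Thesaurus:
    """Deterministic fixture thesaurus; same spec -> identical content."""
    th = Thesaurus()
    if spec.include_table_vocabulary:
        for ui, en, fr, trees, ens, frs in _QUALIFIERS:
            q = Qualifier(ui=ui, labels={"en": en}, tree_numbers=list(trees))
            if "fr" in spec.languages:
                q.labels["fr"] = fr
                if frs:
                    q.synonyms["fr"] = list(frs)
            if ens:
                q.synonyms["en"] = list(ens)
            th.add(q)
        for ui, en, fr, trees, allowed, ens, frs, kind in _DESCRIPTORS:
            d = Descriptor(
                ui=ui,
                kind=RecordKind(kind),
                labels={"en": en},
                tree_numbers=list(trees),
                allowed_qualifiers=list(allowed),
            )
            if "fr" in spec.languages:
                d.labels["fr"] = fr
                if frs:
                    d.synonyms["fr"] = list(frs)
            if ens:
                d.synonyms["en"] = list(ens)
            th.add(d)
    rng = random.Random(spec.seed)
    for i in range(spec.extra_random_descriptors):
        ui = f"D95{i:04d}"
        tree = "R%d.%d.%d" % (
            rng.randrange(10, 99), rng.randrange(100, 999), rng.randrange(100, 999)
        )
        labels = {"en": f"synthetic concept {i:04d}"}
        d = Descriptor(ui=ui, labels=labels, tree_numbers=[tree])
        if "fr" in spec.languages:
            d.labels["fr"] = f"concept synthétique {i:04d}"
        th.add(d)
    th.validate()
    return th


_DEFAULT_THESAURUS: Optional[Thesaurus] = None


def default_thesaurus() -> Thesaurus:
    """Shared instance of the default fixture thesaurus."""
    global _DEFAULT_THESAURUS
    if _DEFAULT_THESAURUS is None:
        _DEFAULT_THESAURUS = build_fixture_thesaurus()
    return _DEFAULT_THESAURUS


def export_fixture(directory: Union[str, Path], spec: FixtureSpec = FixtureSpec()) -> dict:
    """Write the fixture thesaurus XML, translation TSVs and gold JSONL."""
    from .grading import dump_gold

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    th = build_fixture_thesaurus(spec)
    paths = {"thesaurus": directory / "thesaurus.xml", "gold": directory / "gold.jsonl"}
    write_mesh_xml(th, paths["thesaurus"])
    for lang in spec.languages:
        if lang == "en":
            continue
        paths[f"translations_{lang}"] = directory / f"labels_{lang}.tsv"
        write_translations(th, lang, paths[f"translations_{lang}"])
    dump_gold(GOLD_QUESTIONS, paths["gold"])
    return paths


# ---------------------------------------------------------------------------
# single-error perturbations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerturbationPlan:
    error_kind: ErrorKind
    variant: int = 0
    target: Optional[int] = None  # term (or operator) index; None = first that works
    seed: int = 0


def _map_terms(node: QueryNode, fn, counter=None) -> QueryNode:
    """Rebuild a tree applying ``fn(term, index)`` to each term node."""
    if counter is None:
        counter = [0]
    if isinstance(node, TermNode):
        idx = counter[0]
        counter[0] += 1
        return fn(node, idx)
    if isinstance(node, BoolNode):
        return replace(
            node, children=tuple(_map_terms(c, fn, counter) for c in node.children)
        )
    return node


def _swap_operator(node: QueryNode, target: int, counter=None) -> QueryNode:
    """Flip a single AND/OR operator *instance* (an n-ary node holds n-1).

    Swapping instance j of ``op(c0..cn)`` splits the node as left
    associativity dictates: ``a AND b AND c`` with the first instance
    flipped reads ``a OR b AND c``, i.e. ``OR(a, AND(b, c))``.
    """
    if counter is None:
        counter = [0]
    if not isinstance(node, BoolNode):
        return node
    children = tuple(_swap_operator(c, target, counter) for c in node.children)
    op = node.operator
    if op == "NOT":
        return BoolNode(op, children)
    first = counter[0]
    n_here = len(children) - 1
    counter[0] += n_here
    if not (first <= target < first + n_here):
        return BoolNode(op, children)
    j = target - first

    def group(parts: tuple) -> QueryNode:
        return parts[0] if len(parts) == 1 else BoolNode(op, parts)

    flipped = "OR" if op == "AND" else "AND"
    return BoolNode(flipped, (group(children[: j + 1]), group(children[j + 1:])))


def _count_operator_instances(node: QueryNode) -> int:
    if not isinstance(node, BoolNode):
        return 0
    n = len(node.children) - 1 if node.operator in ("AND", "OR") else 0
    return n + sum(_count_operator_instances(c) for c in node.children)


def _descriptor_mutations(
    term: TermNode, kind: ErrorKind, th: Thesaurus
) -> list[TermNode]:
    """Candidate single-term rewrites for a descriptor-level error kind."""
    d = th.descriptors[term.descriptor_ui]
    out: list[TermNode] = []
    if d.kind is RecordKind.PUBLICATION_TYPE:
        if kind is ErrorKind.IRRELEVANT_TERM:
            out.append(TermNode(DECOY_UI))
        return out
    if kind is ErrorKind.UNDERSPEC_DESCRIPTOR:
        anc = th.parent_of(term.descriptor_ui)
        while anc is not None:
            keep_q = term.qualifier_ui if (
                term.qualifier_ui in getattr(anc, "allowed_qualifiers", [])
            ) else None
            out.append(replace(term, descriptor_ui=anc.ui, qualifier_ui=keep_q))
            anc = th.parent_of(anc.ui)
    elif kind is ErrorKind.OVERSPEC_DESCRIPTOR:
        for child in th.children_of(term.descriptor_ui):
            keep_q = term.qualifier_ui if (
                term.qualifier_ui in child.allowed_qualifiers
            ) else None
            out.append(replace(term, descriptor_ui=child.ui, qualifier_ui=keep_q))
    elif kind is ErrorKind.IRRELEVANT_TERM:
        out.append(TermNode(DECOY_UI))
    elif kind is ErrorKind.UNDERSPEC_QUALIFIER:
        if term.qualifier_ui is not None:
            out.append(replace(term, qualifier_ui=None))
    elif kind is ErrorKind.OVERSPEC_QUALIFIER:
        if term.qualifier_ui is None:
            for qui in d.allowed_qualifiers:
                out.append(replace(term, qualifier_ui=qui))
        else:
            for child in th.children_of(term.qualifier_ui):
                out.append(replace(term, qualifier_ui=child.ui))
    return out


def _validated_term_mutations(
    gold: GoldStandard, kind: ErrorKind, thesaurus: Thesaurus, variant: int = 0
) -> list[tuple[int, TermNode]]:
    """(term index, rewrite) options whose lone application grades exactly
    one error of ``kind`` — rewrites colliding with another accepted
    variant are filtered out here.  Cached per (thesaurus, question, kind)."""
    key = (id(thesaurus), gold.question_id, kind, variant)
    cached = _MUTATION_CACHE.get(key)
    if cached is not None:
        return cached
    node = parse(gold.variants[variant], thesaurus, "en")
    terms = extract_terms(node)
    out: list[tuple[int, TermNode]] = []
    for t in range(len(terms)):
        for mutation in _descriptor_mutations(terms[t], kind, thesaurus):
            def rewrite(term, idx, _t=t, _m=mutation):
                return _m if idx == _t else term
            text = serialize(_map_terms(node, rewrite), thesaurus)
            rep = grade(text, gold, thesaurus)
            if rep.counts[kind] == 1 and rep.total == 1:
                out.append((t, mutation))
    _MUTATION_CACHE[key] = out
    return out


_MUTATION_CACHE: dict = {}


def perturb(
    gold: GoldStandard, plan: PerturbationPlan, thesaurus: Thesaurus
) -> str:
    """Return a query differing from a gold variant by exactly the planned error.

    Constructed by inverting the error definition (replace a descriptor by
    an ancestor for under-specification, by a descendant for
    over-specification, by the unrelated decoy for an irrelevant term;
    drop / add-or-narrow a subheading; swap one AND/OR; unbalance a
    bracket or truncate a word) and *verified*: the grader must report
    exactly the planned kind with count one — a rewrite that collides
    with another accepted variant is rejected and the next target tried.
    Raises ``ValueError`` when the plan is inapplicable to the question.
    """
    base_text = gold.variants[plan.variant]
    node = parse(base_text, thesaurus, "en")
    kind = plan.error_kind

    candidates: list[str] = []
    if kind is ErrorKind.SYNTAX_ERROR:
        if ")" in base_text:
            i = base_text.rindex(")")
            candidates.append(base_text[:i] + base_text[i + 1:])
        candidates.append(base_text + "*")
    elif kind is ErrorKind.INCORRECT_OPERATOR:
        n_ops = _count_operator_instances(node)
        targets = [plan.target] if plan.target is not None else range(n_ops)
        for t in targets:
            candidates.append(serialize(_swap_operator(node, t), thesaurus))
    else:
        for t, mutation in _validated_term_mutations(gold, kind, thesaurus, plan.variant):
            if plan.target is not None and t != plan.target:
                continue
            def rewrite(term, idx, _t=t, _m=mutation):
                return _m if idx == _t else term
            candidates.append(serialize(_map_terms(node, rewrite), thesaurus))

    for text in candidates:
        rep = grade(text, gold, thesaurus)
        if rep.counts[kind] == 1 and rep.total == 1:
            return text
    raise ValueError(
        f"error kind {kind.value!r} is not applicable to question "
        f"{gold.question_id!r} (variant {plan.variant})"
    )


def applicable_kinds(gold: GoldStandard, thesaurus: Thesaurus) -> list[ErrorKind]:
    """Error kinds for which a clean single-error perturbation exists."""
    out = []
    for kind in ErrorKind:
        try:
            perturb(gold, PerturbationPlan(kind), thesaurus)
            out.append(kind)
        except ValueError:
            pass
    return out


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------


@dataclass
class TrialScenario:
    """Two-arm end-to-end simulation: per-arm, per-error injection rates.

    ``rates`` maps arm label -> {error kind: probability that this kind is
    *attempted* on a given query}; an attempt on a question where the kind
    is not constructible leaves the query unchanged.  ``arm_queries`` can
    subsample to the analysed per-arm query totals.
    """

    participants: dict[str, int]
    rates: dict[str, dict[ErrorKind, float]]
    questions: Sequence[GoldStandard] = field(default_factory=lambda: GOLD_QUESTIONS)
    questions_per_participant: int = 12
    arm_queries: Optional[dict[str, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for arm, kinds in self.rates.items():
            for kind, p in kinds.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"rate for {arm}/{kind} outside [0, 1]")


def applicability_fraction(
    kind: ErrorKind,
    questions: Sequence[GoldStandard],
    thesaurus: Thesaurus,
) -> float:
    ok = sum(1 for q in questions if kind in applicable_kinds(q, thesaurus))
    return ok / len(questions)


def calibrated_rates(
    target_flag_rates: dict[ErrorKind, float],
    questions: Sequence[GoldStandard],
    thesaurus: Thesaurus,
) -> dict[ErrorKind, float]:
    """Inflate target query-level flag rates by inverse applicability.

    An error kind constructible on only a fraction f of the questions must
    be attempted at rate p/f to be realized at rate ~p overall (capped at 1).
    """
    out = {}
    for kind, p in target_flag_rates.items():
        f = applicability_fraction(kind, questions, thesaurus)
        out[kind] = min(1.0, p / f) if f > 0 else 0.0
    return out


def refine_rates(
    rates: dict[str, dict[ErrorKind, float]],
    targets: dict[str, dict[ErrorKind, float]],
    thesaurus: Thesaurus,
    questions: Sequence[GoldStandard] = None,
    iterations: int = 4,
    pilot_participants: int = 100,
    pilot_seed: int = 202301,
) -> dict[str, dict[ErrorKind, float]]:
    """Fixed-point refinement of attempt rates against graded flag rates.

    The analytic applicability correction ignores second-order losses
    (two sampled error kinds competing for the same term, or a composed
    rewrite being re-classified against another accepted variant), so the
    attempt rates are iteratively rescaled by target/realized using pilot
    simulations at a fixed internal seed.  Deterministic.
    """
    if questions is None:
        questions = GOLD_QUESTIONS
    rates = {arm: dict(kinds) for arm, kinds in rates.items()}
    for it in range(iterations):
        pilot = TrialScenario(
            participants={arm: pilot_participants for arm in rates},
            rates=rates,
            questions=questions,
            seed=pilot_seed + it,
        )
        subs, _ = simulate_trial(pilot, thesaurus)
        triples = grade_submissions(subs, questions, thesaurus)
        n = {arm: 0 for arm in rates}
        flagged = {arm: {k: 0 for k in ErrorKind} for arm in rates}
        for arm, _, rep in triples:
            n[arm] += 1
            for kind, f in rep.flags().items():
                flagged[arm][kind] += f
        for arm in rates:
            for kind in ErrorKind:
                target = targets[arm].get(kind, 0.0)
                realized = flagged[arm][kind] / n[arm]
                if target <= 0.0:
                    rates[arm][kind] = 0.0
                elif realized > 0.0:
                    rates[arm][kind] = min(1.0, rates[arm][kind] * target / realized)
    return rates


_SCENARIO_RATE_CACHE: dict = {}


def table_calibrated_scenario(
    thesaurus: Thesaurus, seed: int = 0
) -> TrialScenario:
    """Scenario whose injection rates target the observed per-arm flag rates.

    Calibration (analytic applicability correction plus fixed-point
    refinement) runs once per thesaurus and is independent of ``seed``,
    which only drives the trial sampling itself.
    """
    cache_key = id(thesaurus)
    rates = _SCENARIO_RATE_CACHE.get(cache_key)
    if rates is None:
        targets = {}
        rates = {}
        for i, arm in enumerate(TRIAL_ARMS):
            targets[arm] = {
                kind: TRIAL_FLAG_COUNTS[kind.value][i] / TRIAL_ARM_TOTALS[i]
                for kind in ErrorKind
            }
            rates[arm] = calibrated_rates(targets[arm], GOLD_QUESTIONS, thesaurus)
        rates = refine_rates(rates, targets, thesaurus)
        _SCENARIO_RATE_CACHE[cache_key] = rates
    return TrialScenario(
        participants={TRIAL_ARMS[0]: 20, TRIAL_ARMS[1]: 22},
        rates={arm: dict(kinds) for arm, kinds in rates.items()},
        arm_queries={TRIAL_ARMS[0]: TRIAL_ARM_TOTALS[0], TRIAL_ARMS[1]: TRIAL_ARM_TOTALS[1]},
        seed=seed,
    )


def _inject(
    gold: GoldStandard,
    kinds: list[ErrorKind],
    thesaurus: Thesaurus,
) -> tuple[str, list[ErrorKind]]:
    """Apply several error kinds to one gold query, best effort.

    Each term offers two mutation slots — its descriptor and its
    qualifier — because a broadened descriptor and a dropped subheading
    on the same term are flagged independently by the grader.  An
    irrelevant-term replacement consumes both slots (an unrelated
    descriptor suppresses qualifier grading).  Kinds that cannot be
    realized on this question are skipped.  Returns the final query text
    and the kinds actually applied.
    """
    node = parse(gold.variants[0], thesaurus, "en")
    desc_used: set[int] = set()
    qual_used: set[int] = set()
    applied: list[ErrorKind] = []
    syntax = False

    qualifier_kinds = (ErrorKind.UNDERSPEC_QUALIFIER, ErrorKind.OVERSPEC_QUALIFIER)
    descriptor_kinds = (
        ErrorKind.OVERSPEC_DESCRIPTOR,
        ErrorKind.UNDERSPEC_DESCRIPTOR,
        ErrorKind.IRRELEVANT_TERM,
    )
    # scarcest slots first: qualifier-level kinds, then descriptor-level
    # (the decoy replacement is most flexible, so it goes last)
    order = [k for k in qualifier_kinds + descriptor_kinds + (
        ErrorKind.INCORRECT_OPERATOR, ErrorKind.SYNTAX_ERROR) if k in kinds]

    for kind in order:
        if kind is ErrorKind.SYNTAX_ERROR:
            syntax = True
            continue
        if kind is ErrorKind.INCORRECT_OPERATOR:
            if _count_operator_instances(node) > 0:
                node = _swap_operator(node, 0)
                applied.append(kind)
            continue
        for t, mutation in _validated_term_mutations(gold, kind, thesaurus):
            if kind in qualifier_kinds:
                if t in qual_used:
                    continue
                slots = [qual_used]
            elif kind is ErrorKind.IRRELEVANT_TERM:
                if t in desc_used or t in qual_used:
                    continue
                slots = [desc_used, qual_used]
            else:
                if t in desc_used:
                    continue
                slots = [desc_used]
                # an ancestor/descendant rewrite that had to drop the
                # subheading occupies the qualifier slot as well
                gold_term = extract_terms(parse(gold.variants[0], thesaurus, "en"))[t]
                if gold_term.qualifier_ui is not None and mutation.qualifier_ui is None:
                    if t in qual_used:
                        continue
                    slots.append(qual_used)

            def rewrite(term, idx, _t=t, _m=mutation, _kind=kind):
                if idx != _t:
                    return term
                if _kind in qualifier_kinds:
                    # graft only the qualifier change onto the current term
                    return replace(term, qualifier_ui=_m.qualifier_ui)
                if term.qualifier_ui is not None and _m.qualifier_ui is None and _kind is not ErrorKind.IRRELEVANT_TERM:
                    return _m
                if _kind is ErrorKind.IRRELEVANT_TERM:
                    return _m
                return replace(term, descriptor_ui=_m.descriptor_ui)

            node = _map_terms(node, rewrite)
            for s in slots:
                s.add(t)
            applied.append(kind)
            break

    text = serialize(node, thesaurus)
    if syntax:
        text = (text[: text.rindex(")")] + text[text.rindex(")") + 1:]) if ")" in text else text + "*"
        applied.append(ErrorKind.SYNTAX_ERROR)
    return text, applied


def simulate_trial(
    scenario: TrialScenario, thesaurus: Thesaurus
) -> tuple[list[Submission], list[dict]]:
    """Sample a full two-arm trial; deterministic under the scenario seed.

    Returns submissions plus truth records (the error kinds injected into
    each query).  Error kinds are sampled independently per type per query.
    """
    rng = random.Random(scenario.seed)
    submissions: list[Submission] = []
    truth: list[dict] = []
    for arm in sorted(scenario.participants):
        n_part = scenario.participants[arm]
        rates = scenario.rates.get(arm, {})
        rows = []
        for p in range(1, n_part + 1):
            pid = f"{arm[:2].upper()}{p:03d}"
            for q in scenario.questions[: scenario.questions_per_participant]:
                kinds = [k for k in ErrorKind if rng.random() < rates.get(k, 0.0)]
                text, applied = _inject(q, kinds, thesaurus)
                rows.append((pid, q, text, applied))
        if scenario.arm_queries and arm in scenario.arm_queries:
            keep = scenario.arm_queries[arm]
            if keep < len(rows):
                idx = sorted(rng.sample(range(len(rows)), keep))
                rows = [rows[i] for i in idx]
        for pid, q, text, applied in rows:
            submissions.append(Submission(pid, arm, q.question_id, text))
            truth.append(
                {
                    "participant_id": pid,
                    "arm": arm,
                    "question_id": q.question_id,
                    "injected": [k.value for k in applied],
                }
            )
    return submissions, truth


def submissions_to_tsv(submissions: Sequence[Submission]) -> str:
    lines = []
    for s in submissions:
        seconds = "" if s.seconds is None else f"{s.seconds:g}"
        lines.append("\t".join([s.participant_id, s.arm, s.question_id, s.query_text, seconds]).rstrip("\t"))
    return "\n".join(lines) + "\n"


def grade_submissions(
    submissions: Sequence[Submission],
    questions: Sequence[GoldStandard],
    thesaurus: Thesaurus,
    language: str = "en",
) -> list[tuple[str, str, ErrorReport]]:
    """Grade a batch of submissions, yielding summarize()-ready triples."""
    by_id = {q.question_id: q for q in questions}
    out = []
    for s in submissions:
        gold = by_id.get(s.question_id)
        if gold is None:
            raise ValueError(f"unknown question id {s.question_id!r}")
        out.append((s.arm, gold.difficulty, grade(s.query_text, gold, thesaurus, language)))
    return out
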