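"""Grade candidate queries against a gold standard with the error taxonomy.

Each candidate is aligned to the accepted query variants; the report
counts irrelevant terms, over-/under-specified descriptors and
subheadings, operator misuse, and syntax errors.  A perfect query has
zero errors.
"""

from meshlingua import GOLD_QUESTIONS, build_fixture_thesaurus, grade

th = build_fixture_thesaurus()
question = GOLD_QUESTIONS[1]  # "Alopecia areata prevention"
print("question:", question.question_text["en"])
print("gold:    ", question.variants[0])

candidates = [
    "alopecia areata/prevention and control",  # the gold query itself
    "alopecia areata",                         # subheading missing
    "alopecia AND prevention",                 # too broad + an extra term
    "(alopecia areata/prevention and control", # unbalanced bracket
]
for text in candidates:
    rep = grade(text, question, th)
    errors = {k.value: v for k, v in rep.counts.items() if v}
    verdict = "perfect" if rep.perfect else errors
    print(f"  {text!r:55} -> {verdict}")
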