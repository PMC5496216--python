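"""Find MeSH terms in French, assemble a Boolean query, emit PubMed syntax.

Walks the front half of the toolkit: autocomplete lookup in the user's
language, query parsing with subheadings, synonym completion for recall,
and serialization to the PubMed advanced-search dialect.
"""

from meshlingua import (
    build_fixture_thesaurus,
    build_index,
    expand_synonyms,
    parse,
    serialize,
    suggest,
)

th = build_fixture_thesaurus()

# A French speaker types "pelade" — the suggester returns the controlled
# vocabulary record (alopecia areata) it maps to.
fr_index = build_index(th, "fr")
print("suggestions for 'pelade':")
for s in suggest(fr_index, "pelade", limit=3):
    print(f"  {s.ui}  {s.display_label}  (match class {s.match_class})")

# Assemble a query in French, with a subheading, and emit PubMed syntax.
node = parse("pelade/prévention et contrôle", th, language="fr")
print("\nPubMed query:", serialize(node, th))

# Synonym completion ORs entry terms in as free text to maximize recall;
# the MeSH term itself is untouched.
node = parse("vitamin D AND blood chemical analysis", th)
print("\nexpanded:", serialize(expand_synonyms(node, th), th))
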