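"""Match the firearm taxonomy in a note and cut the keyphrase snippet.

Builds one short clinical-style note, finds taxonomy matches with
longest-match-first overlap resolution, and extracts the 35-words-each-side
snippet the classifier would consume.
"""

import fsnlp

note = (
    "Routine follow up. Veteran reports he cleaned his SNIPER RIFLE this weekend "
    "and keeps a 9mm Glock in the nightstand. Denies distress. Plan unchanged."
)

lexicon = fsnlp.Lexicon.default()
print(f"taxonomy phrases: {len(lexicon)}")

matches = fsnlp.find_term_matches(note, lexicon, note_id="demo")
for m in matches:
    print(f"match: {m.term_text!r} at tokens {m.token_start}:{m.token_end}, chars {m.char_span}")
# Two matches: 'sniper rifle' (the inner 'rifle' is suppressed by the
# longest-match rule) and '9 mm glock' (the fused '9mm' is split to match
# the spaced taxonomy form).

snippet = fsnlp.extract_snippet(note, matches[0])
print(f"snippet of {len(snippet.tokens)} tokens, keyphrase at offset {snippet.keyphrase_offset}")
print(" ".join(snippet.tokens))
# The snippet truncates at the note start, so the keyphrase offset (< 35)
# records how many context words actually precede it.
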