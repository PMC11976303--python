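# Special-character canonicalization map applied after Unicode NFKC.
# Two tab-separated columns: source codepoint (U+XXXX) and replacement text.
# NFKC already folds fullwidth ASCII forms; this table covers typographic
# variants NFKC leaves alone.  The multiplication sign U+00D7 is the
# canonical hybrid sign and is deliberately absent (identity).
# Escapes in the replacement column: \s = space, \0 = delete.
U+2018	'
U+2019	'
U+201A	'
U+201B	'
U+201C	"
U+201D	"
U+201E	"
U+2032	'
U+2033	"
U+2010	-
U+2011	-
U+2012	-
U+2013	-
U+2014	-
U+2015	-
U+2212	-
U+00A0	\s
U+2007	\s
U+202F	\s
U+FEFF	\0
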