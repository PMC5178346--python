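# Default stop-list for the tagging lexicon.
# One lowercase surface form per line; '#' starts a comment.
# These forms collide with ordinary record-keeping language in
# isolation-source fields and would tag almost every record.
# The list is a curated artifact; edit freely or pass --stoplist.
area
bed
field
gas
material
matter
object
part
plant  # ambiguous with industrial plant
root   # ambiguous with root of a hierarchy / square root
sample
site
spring # ambiguous with the season
surface
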