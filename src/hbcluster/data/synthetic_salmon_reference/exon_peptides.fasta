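>alpha.exon1
MSFSNVHWFLVILQSDVRELGDIQEIFCTEC
>alpha.exon2
MCMTGIPPSFHHYRITYRPLDMSNVQHWNKRAHHRAQRMNDIFTGQHARCREFTSWPPMQKWMFPIDQ
>alpha.exon3
GSQLFRKRLQQNRCGNIHNLMVYMIKFSQVNGASQLTVWGDQWY
>beta.exon1
MGFHFMGLIIDSFIMNTYWTNYTNFCACGA
>beta.exon2
WPQGSSADKAHTKCNFWTEYCWHSCENLDYKPQMPRMQMDEYSKAPFHIAMHGNPSLPEGYCQGHCRIRSQDHC
>beta.exon3
PGPSMNNCTMYERCIFYFENYTRMNWFYVPPPIPGKSTNIREEH
>beta_nonbohr.exon1
MGFHFMGLIIDSFIMNTYETAYTNFCACLA
>beta_nonbohr.exon2
WPLGSSADKAHSKCNTWTEYCDHSCENLDRKPAMPRMQMDEYHKAPFHIAMAGNPSLPEGYCAGHCRIRSQDHC
>beta_nonbohr.exon3
DGPSMNNCTMYERCIFYFENQTRMNFFYHMPPIPSKSTNIREF
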