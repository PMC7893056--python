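# Default English stopword list applied when building neighbor sets.
a an and are as at be been but by can could did do does for from had has
have he her hers him his how i if in into is it its may might more most
must my no nor not of on or our ours shall she should so some such than
that the their theirs them then there these they this those to too us
was we were what when where which while who whom why will with would you
your yours
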