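# Two-chain complex benchmark list: 4-char PDB code + two chain IDs per entry
1acbEI	1e96AB	1h2sAB	1kxqAH	1otsAC	1t9gDS	1x3wAB	2ayoAB
1agrAE	1eaiBD	1h4lAD	1kz7AB	1oxbAB	1ta3BA	1x86AB	2b3tBA
1aroPL	1ebdBC	1h59AB	1kzyCA	1oyvAI	1tafAB	1xb2AB	2b59AB
1avaAC	1eerBA	1h6kAX	1l4dAB	1oyvBI	1tdqAB	1xd3AB	2b5iBA
1avgHI	1efnAB	1h9hEI	1l6xAB	1p5vAB	1te1AB	1xdkBA	2b5iCA
1avwAB	1ewyAC	1he1AC	1l7vAC	1p8vAC	1th1AC	1xdtTR	2bcjAQ
1axiBA	1f02IT	1he8AB	1ldjAB	1p9mCB	1th8AB	1xg2AB	2bfxAD
1ay7AB	1f34AB	1hl6BA	1lfdBA	1p9mAB	1tmqAB	1xk4AC	2bh1AX
1b0nAB	1f3vBA	1hx1AB	1lpbBA	1pk1AB	1tnrAR	1xl3AC	2bkhAB
1b34AB	1f5qAB	1i1rAB	1ltxAR	1ppfEI	1tocBR	1xouBA	2bkkAB
1b6cAB	1f60AB	1i2mBA	1m1eAB	1pqzAB	1tt5AB	1xqsAC	2bkrAB
1blxAB	1f6fBA	1i7wAB	1m27AC	1pvhAB	1tueAB	1xtgAB	2bo9AB
1bmlCA	1f6mAC	1i8lAC	1m2vBA	1pxvAC	1tx4AB	1xu1AR	2bseAE
1bndAB	1f93BE	1iarBA	1m9fAD	1qa9AB	1tx6AI	1y4hAC	2btfAP
1buhAB	1fbvAC	1ib1AE	1ma9AB	1qavBA	1txqAB	1y64AB	2c1mAB
1buiAC	1fccAC	1ibrBA	1mbxAC	1qbkBC	1tygAB	1y8xAB	2c5dAC
1bvnPT	1fleEI	1iraYX	1moxAC	1qo3AC	1u0sYA	1ycsAB	2ckhAB
1bzqAL	1fm9AD	1itbBA	1mq8AB	1r0rEI	1u7fAB	1yvbAI	2ey4AE
1c1yAB	1foeAB	1ixsBA	1mvfAE	1r1kAD	1uadAC	1z0jAB	2ey4AC
1c4zAD	1fqjAB	1j2jAB	1mzwAB	1r4aAE	1ueaAB	1z2cBA	2f9dAP
1c9pAB	1fqjCA	1jatAB	1n0wAB	1r8sAE	1ughEI	1z3eAB	2fi4EI
1cd9BA	1fr2BA	1jdhAB	1nexBA	1rp3AB	1ujwAB	1z3gHA	2g45AB
1choEI	1fs1BA	1jiwPI	1nf3AC	1s1qAB	1ukvGY	1z5yED	2gooAC
1clvAI	1fyhAB	1jk9BA	1nmuAB	1s3sBH	1ul1XA	1z92AB	2gy7AB
1cseEI	1g3nAB	1jmaAB	1npeAB	1s4yBA	1us7AB	1zbdAB	2hppHP
1cxzAB	1g3nAC	1jowBA	1nqlAB	1s6vAB	1usuAB	1zbxAB	2mtaCA
1d2zBA	1g4uSR	1jtdAB	1nt2BA	1sbbBC	1uuzAD	1zc3AD	2sniEI
1d3bAB	1g6vAK	1jtgAB	1nunBA	1sgfGB	1uw4BA	1zlhAB	2trcBP
1d4xAG	1g73AC	1jtpAL	1nvuSQ	1sgpEI	1uzxAB	1zm2AB	3fapAB
1d6rAI	1gc1GC	1jw9BD	1nw9BA	1shwAB	1v5iAB	2a19BA	3hhrCA
1devAB	1gcqAC	1k5dAB	1o6sAB	1shyBA	1v74AB	2a41AC	3proAC
1df9AC	1gh6BA	1k8rAB	1o94AC	1shzAC	1vetAB	2a42AB	3sicEI
1dfjEI	1ghqAB	1k90AD	1oc0AB	1sppAB	1vg0AB	2a5dBA	3ygsCP
1dhkAB	1gl0EI	1kacAB	1oeyJA	1sq0AB	1w1iAF	2a5tAB	4htcHI
1dkfBA	1gl1AI	1kg0BC	1ofhAG	1sq2LN	1w98AB	2a5yBA	4sgbEI
1dkgDA	1gl4AB	1kgyAE	1ofuAX	1stfEI	1wmhAB	2a78BA	1dmlAB
1glbFG	1ki1BA	1ohzAB	1sv0AC	1wmiAB	2ajfAE	1dn1AB	1go4AG
1kpsAB	1ol5AB	1svxBA	1wpxAB	2apoAB	1dowAB	1gpwAB	1kshAB
1oo0AB	1syxAB	1wq1RG	2assBA	1ds6AB	1gvnBA	1ktkEA	1ophAB
1t0fAC	1wr6AE	2assBC	1dtdAB	1gxdAC	1ktzBA	1or7AC	1t6bXY
1wrdAB	2auhAB	1e44BA	1gzsAB	1ku6AB	1oryAB	1t6gAC	1wywAB
2aw2AB
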