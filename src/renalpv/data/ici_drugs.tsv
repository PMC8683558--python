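# Immune checkpoint inhibitors: name variant <TAB> canonical drug id <TAB> class
# Generic names and US brand names for the eight approved ICIs.
nivolumab	nivolumab	anti-PD-1
opdivo	nivolumab	anti-PD-1
pembrolizumab	pembrolizumab	anti-PD-1
keytruda	pembrolizumab	anti-PD-1
cemiplimab	cemiplimab	anti-PD-1
cemiplimab-rwlc	cemiplimab	anti-PD-1
libtayo	cemiplimab	anti-PD-1
atezolizumab	atezolizumab	anti-PD-L1
tecentriq	atezolizumab	anti-PD-L1
avelumab	avelumab	anti-PD-L1
bavencio	avelumab	anti-PD-L1
durvalumab	durvalumab	anti-PD-L1
imfinzi	durvalumab	anti-PD-L1
ipilimumab	ipilimumab	anti-CTLA-4
yervoy	ipilimumab	anti-CTLA-4
tremelimumab	tremelimumab	anti-CTLA-4
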