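# The structured-action grammar

This is the normative grammar implemented by `synthaction.actionlang`.  The
published description of the format shows representative examples per action
rather than a complete grammar, so the EBNF below is a covering
reconstruction: every published example parses under it, and the serializer
emits exactly this surface form.  Parsing is case-insensitive on action
keywords; serialization always emits the canonical uppercase keyword.

```ebnf
sequence     = clause , { ";" , sp , clause } , "." ;
clause       = keyword , [ payload ] , [ at-mod ] , [ for-mod ] ;
keyword      = "ADD" | "COLLECTLAYER" | "CONCENTRATE" | "DEGAS" | "DRYSOLID"
             | "DRYSOLUTION" | "EXTRACT" | "FILTER" | "FOLLOWOTHERPROCEDURE"
             | "MAKESOLUTION" | "MICROWAVE" | "OTHERLANGUAGE" | "PARTITION"
             | "PH" | "PHASESEPARATION" | "INVALIDACTION" | "PURIFY"
             | "QUENCH" | "RECRYSTALLIZE" | "NOACTION" | "REFLUX"
             | "SETTEMPERATURE" | "SONICATE" | "STIR" | "TRITURATE" | "WAIT"
             | "WASH" | "YIELD" ;

(* payload shape depends on the keyword *)
payload      = bare-item          (* ADD, YIELD *)
             | with-items         (* MAKESOLUTION, QUENCH, WASH, EXTRACT,
                                     PARTITION, TRITURATE, RECRYSTALLIZE,
                                     DEGAS *)
             | over-item          (* DRYSOLUTION *)
             | keep-phase         (* FILTER, COLLECTLAYER *)
             | purify-solvents    (* PURIFY *)
             | temperature        (* SETTEMPERATURE *)
             | free-text ;        (* PH, NOACTION, INVALIDACTION,
                                     OTHERLANGUAGE, PHASESEPARATION,
                                     FOLLOWOTHERPROCEDURE *)
             (* CONCENTRATE, DRYSOLID, MICROWAVE, REFLUX, SONICATE, STIR,
                WAIT take no payload, only the optional modifiers *)

bare-item    = item ;
with-items   = "with" , item , { "and" , item } ;
over-item    = "over" , item ;
item         = "SLN" | name , [ "(" , amount , ")" ] ;
keep-phase   = "keep" , ( "precipitate" | "filtrate"      (* FILTER *)
                        | "organic" | "aqueous" ) ;       (* COLLECTLAYER *)
purify-solvents = ":" , sp , solvent , { ":" , solvent } ,
                  [ "(" , ratio , ")" ] ;
at-mod       = "at" , temperature ;
for-mod      = "for" , duration ;
```

Notes and tie-breaks:

* `SLN` is a reserved token back-referencing the solution produced by the
  preceding MAKESOLUTION clause; it is never a chemical name.
* Item lists split only on top-level `" and "` — an `and` inside
  parentheses belongs to the chemical name.
* A trailing parenthetical is an **amount** only when it contains a digit
  and at least two tokens (`(200 mg)`, `(10 mL)`).  `(THF)` and oxidation
  states like `(0)` in `tetrakis(triphenylphosphine)palladium(0)` remain
  part of the name.  Amounts are preserved verbatim.
* The PURIFY ratio (e.g. `(3:1)`) is modeled as optional trailing text; the
  published examples never show one together with solvents, so this slot is
  a documented extension.
* Chemical names are case-significant and preserved verbatim.
* A missing final period is tolerated on input and always emitted on
  output; clause separators normalize to `"; "`.
* Unknown keywords: strict mode raises; lenient mode yields an
  INVALIDACTION clause whose `free_params` holds the raw segment.
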