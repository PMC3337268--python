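<?xml version="1.0" encoding="utf-8"?>
<rdf:RDF
   xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
   xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"
>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#ModeOfAction">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>ModeOfAction</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/toxlift/endpoint#TestResult"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#TestResult">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:comment>The recorded outcome of a toxicity study.</rdfs:comment>
    <rdfs:label>TestResult</rdfs:label>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#Sex">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>Sex</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/toxlift/endpoint#TestSystem"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#ToxicityStudyType">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:comment>Category of toxicity study an endpoint belongs to.</rdfs:comment>
    <rdfs:label>ToxicityStudyType</rdfs:label>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#SubAcute">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>SubAcute</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/toxlift/endpoint#RepeatedDoseToxicity"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#ToxicityMeasure">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>ToxicityMeasure</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/toxlift/endpoint#TestResult"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#InVitroBacterialMutagenicity">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>InVitroBacterialMutagenicity</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/toxlift/endpoint#ToxicityStudyType"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#TargetSite">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>TargetSite</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/toxlift/endpoint#TestResult"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#TestCall">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>TestCall</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/toxlift/endpoint#TestResult"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#Carcinogenicity">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>Carcinogenicity</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/toxlift/endpoint#ToxicityStudyType"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#TestSystem">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:comment>The biological system and exposure design of a study.</rdfs:comment>
    <rdfs:label>TestSystem</rdfs:label>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#InVivoMicronucleusMutagenicity">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>InVivoMicronucleusMutagenicity</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/toxlift/endpoint#ToxicityStudyType"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#hasTestResult">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#ObjectProperty"/>
    <rdfs:domain rdf:resource="http://example.org/toxlift/endpoint#ToxicityStudyType"/>
    <rdfs:range rdf:resource="http://example.org/toxlift/endpoint#TestResult"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#RepeatedDoseToxicity">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>RepeatedDoseToxicity</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/toxlift/endpoint#ToxicityStudyType"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#RouteOfExposure">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>RouteOfExposure</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/toxlift/endpoint#TestSystem"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#hasTestSystem">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#ObjectProperty"/>
    <rdfs:domain rdf:resource="http://example.org/toxlift/endpoint#ToxicityStudyType"/>
    <rdfs:range rdf:resource="http://example.org/toxlift/endpoint#TestSystem"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#Species">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>Species</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/toxlift/endpoint#TestSystem"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#Chronic">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>Chronic</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/toxlift/endpoint#RepeatedDoseToxicity"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#AquaticToxicity">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>AquaticToxicity</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/toxlift/endpoint#ToxicityStudyType"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Ontology"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#Strain">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>Strain</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/toxlift/endpoint#TestSystem"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://example.org/toxlift/endpoint#SubChronic">
    <rdf:type rdf:resource="http://www.w3.org/2002/07/owl#Class"/>
    <rdfs:label>SubChronic</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/toxlift/endpoint#RepeatedDoseToxicity"/>
  </rdf:Description>
</rdf:RDF>
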